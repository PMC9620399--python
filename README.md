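# rnaweave

Automated design of single-stranded RNA wireframe nanostructures.
Given a 3D wireframe mesh, `rnaweave` produces:

1. **Routing** — a spanning tree of the mesh, a cyclic strand traversal
   that covers every tree edge twice in antiparallel directions, and a
   kissing-loop hairpin pair for every discarded (non-tree) edge.
   Connections at each vertex follow the cyclic port order on a small
   sphere, so the vertex matchings never cross and the closed routing is
   an unknot by construction; a knot-determinant diagnostic
   (`|Δ(-1)| = 1` is necessary for the unknot) guards regressions.
2. **Embedding** — every edge rendered as a rigid A-form helix
   (0.281 nm rise, 32.7°/bp, 1.15 nm radius by default), kissing-loop
   edges split into two coaxial semi-helices joined by a 6-bp loop-loop
   duplex, per-edge rotation phases and per-vertex unpaired linker
   counts chosen by a seeded coordinate-descent optimizer, and
   per-nucleotide 3D coordinates.
3. **Structure files** — the versioned `snac` text format (sequence +
   layered dot-bracket structure + coordinates), plus FASTA and Vienna
   dot-bracket exports.
4. **Sequence design** — orthogonal 6-base kissing-loop pairs
   (pairwise Hamming ≥ 3), GC-bounded complementary stem fill, G·U
   wobbles every 8 bp, a forbidden-pattern screen (AAAA/CCCC/GGGG/UUUU
   and 6-runs of K/M/R/S/W/Y), and a T7 DNA template
   (`GAC` + `TAATACGACTCACTATAG` + body + 15 nt tail) with PCR primers.
5. **oxDNA export** — classic topology + configuration input files.

Built-in meshes: `tetrahedron`, `bipyramid`, `prism_triangulated`,
`cube`, `dodecahedron`, `grid` (arbitrary nx×ny×nz lattices).  External
meshes load from Wavefront OBJ (`v`/`f`/`l` records, coordinates in nm
or rescaled via `--units`).

## CLI

The pipeline runs as three inspectable stages (or `all` in one go):

```sh
rnaweave route  --builtin tetrahedron --seed 1 --out out/   # mesh -> snac (N placeholders) + routing report
rnaweave design --snac out/tetrahedron.snac --seed 1 --out out/   # + sequence, FASTA, DNA template
rnaweave export --snac out/tetrahedron_designed.snac --out out/   # -> oxDNA .top/.conf
rnaweave all    --builtin bipyramid --seed 2 --out out/
rnaweave validate --mesh model.obj
```

Every stage writes a manifest (seeds, parameters, version) sufficient
to reproduce its outputs byte-identically.  Helix parameters and
sequence constraints can be overridden with `--config config.yaml`
(keys `helix:` and `constraints:` mapping onto `HelixParams` and
`SequenceConstraints` fields).

## Library

```python
import rnaweave as rw

mesh = rw.builtin_mesh("prism_triangulated", edge_scale=10.0)
plan = rw.route(mesh, rw.spanning_tree(mesh))          # 7 kissing loops
emb = rw.embed_design(mesh, plan, seed=1)
strand = rw.build_strand_model(emb)
ens = rw.generate_kl_ensemble(len(strand.kl_blocks()), seed=1)
res = rw.design_sequence(strand, ens, seed=1)
tpl = rw.build_dna_template(res.sequence, tail_seed=1)
```

## Notes

- The `snac` grammar used here is this package's own versioned dialect
  (header, sequence, structure, one `x y z` line per nucleotide).
- The phase/linker optimizer objective is a documented stand-in:
  per-transition backbone gap deviation plus a weighted angular
  mismatch and a small per-linker penalty.
- Coordinates are idealized rigid helices; relaxation is delegated to
  oxDNA after export.
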