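"""Constrained primary-sequence design (the snacseq stage).

Kissing-loop pairing regions get mutually orthogonal 6-base sequences;
stems are filled with complementary random bases (GC-bounded) and then
G-U wobbles are substituted at fixed base-pair intervals so the dsDNA
template is not self-complementary.  Forbidden patterns: homopolymer
runs of 4 (AAAA, CCCC, GGGG, UUUU) and 6-runs of the two-letter IUPAC
classes K, M, R, S, W, Y.  The DNA template is
cap (GAC) + T7 promoter (TAATACGACTCACTATAG) + body + 15 nt tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import StrandModel

__all__ = [
    "SequenceConstraints",
    "KissingLoopEnsemble",
    "DnaTemplate",
    "DesignResult",
    "SequenceDesignError",
    "violates_constraints",
    "generate_kl_ensemble",
    "apply_wobbles",
    "design_sequence",
    "build_dna_template",
    "revcomp_rna",
    "revcomp_dna",
    "wallace_tm",
    "CAP",
    "T7_PROMOTER",
    "TAIL_LENGTH",
]

CAP = "GAC"
T7_PROMOTER = "TAATACGACTCACTATAG"
TAIL_LENGTH = 15

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

IUPAC_CLASSES = {
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "Y": frozenset("CU"),
}


class SequenceDesignError(RuntimeError):
    pass


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMP[b] for b in reversed(seq))


def revcomp_dna(seq: str) -> str:
    return "".join(_DNA_COMP[b] for b in reversed(seq))


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), degrees C."""
    at = sum(1 for b in seq if b in "AT")
    gc = sum(1 for b in seq if b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass
class SequenceConstraints:
    """Forbidden-pattern and composition rules for designed sequences."""

    homopolymer_run: int = 4
    class_run: int = 6
    wobble_interval: int = 8  # bp between consecutive G-U wobbles in a stem
    gc_min: float = 0.4
    gc_max: float = 0.65
    min_hamming: int = 3  # kissing-loop orthogonality threshold

    def __post_init__(self) -> None:
        if self.wobble_interval < 2:
            raise ValueError("wobble_interval must be >= 2")


def violates_constraints(
    seq: str,
    constraints: SequenceConstraints | None = None,
    alphabet: str = "RNA",
) -> list[tuple[str, int]]:
    """All maximal forbidden-pattern windows in ``seq``.

    Returns ``(pattern, start)`` tuples, e.g. ``("AAAA", 1)`` for a
    homopolymer run or ``("WWWWWW", 0)`` for a 6-run of the A/U class.
    Empty list iff the sequence is clean.
    """
    constraints = constraints or SequenceConstraints()
    u = "U" if alphabet == "RNA" else "T"
    valid = set("ACG") | {u}
    bad = set(seq) - valid
    if bad:
        raise ValueError(f"invalid {alphabet} characters: {sorted(bad)}")

    def runs(members) -> list[tuple[int, int]]:
        out = []
        start = None
        for i, b in enumerate(seq):
            if b in members:
                if start is None:
                    start = i
            elif start is not None:
                out.append((start, i - start))
                start = None
        if start is not None:
            out.append((start, len(seq) - start))
        return out

    violations: list[tuple[str, int]] = []
    for base in sorted(valid):
        for start, length in runs({base}):
            if length >= constraints.homopolymer_run:
                label = (base if base != u else "U" if alphabet == "RNA" else "T")
                violations.append((label * constraints.homopolymer_run, start))
    for cls in sorted(IUPAC_CLASSES):
        members = {b if b != "U" else u for b in IUPAC_CLASSES[cls]}
        for start, length in runs(members):
            if length >= constraints.class_run:
                violations.append((cls * constraints.class_run, start))
    return sorted(violations, key=lambda v: (v[1], v[0]))


# ---------------------------------------------------------------------------
# Kissing-loop ensembles
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class KissingLoopEnsemble:
    """Mutually orthogonal kissing-loop pairs (loop_b = revcomp(loop_a))."""

    pairs: list[tuple[str, str]]
    provenance: list[str] = field(default_factory=list)
    min_hamming: int = 3
    loop_len: int = 6

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["generated"] * len(self.pairs)

    def all_loops(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]

    def validate(self, constraints: SequenceConstraints | None = None) -> list[str]:
        """Exhaustive invariant check (independent of the generator)."""
        problems = []
        for a, b in self.pairs:
            if len(a) != self.loop_len or len(b) != self.loop_len:
                problems.append(f"loop length != {self.loop_len}: {a}/{b}")
            if revcomp_rna(a) != b:
                problems.append(f"not reverse complements: {a}/{b}")
            for s in (a, b):
                if violates_constraints(s, constraints):
                    problems.append(f"forbidden pattern in loop {s}")
        loops = self.all_loops()
        for i in range(len(loops)):
            for j in range(i + 1, len(loops)):
                if _hamming(loops[i], loops[j]) < self.min_hamming:
                    problems.append(
                        f"loops too similar: {loops[i]} vs {loops[j]} "
                        f"(Hamming < {self.min_hamming})"
                    )
        return problems

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("loop_a\tloop_b\tprovenance\n")
            for (a, b), prov in zip(self.pairs, self.provenance):
                fh.write(f"{a}\t{b}\t{prov}\n")

    @classmethod
    def from_tsv(cls, path: str, min_hamming: int = 3) -> "KissingLoopEnsemble":
        pairs, prov = [], []
        with open(path) as fh:
            header = fh.readline()
            for ln in fh:
                a, b, p = ln.split()
                pairs.append((a, b))
                prov.append(p)
        return cls(pairs=pairs, provenance=prov, min_hamming=min_hamming)


def generate_kl_ensemble(
    n: int,
    constraints: SequenceConstraints | None = None,
    seed: int = 0,
    min_hamming: int | None = None,
    loop_len: int = 6,
    literature_pairs: list[tuple[str, str]] | None = None,
    max_attempts: int = 50000,
) -> KissingLoopEnsemble:
    """Generate ``n`` mutually orthogonal kissing-loop pairs (seeded).

    Optional ``literature_pairs`` are injected ahead of generated ones
    and count toward ``n``.  Raises :class:`SequenceDesignError` if the
    orthogonality threshold proves infeasible within the search budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    constraints = constraints or SequenceConstraints()
    m = min_hamming if min_hamming is not None else constraints.min_hamming
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))

    pairs: list[tuple[str, str]] = []
    provenance: list[str] = []
    accepted: list[str] = []
    for a, b in literature_pairs or []:
        if revcomp_rna(a) != b:
            raise ValueError(f"literature pair not complementary: {a}/{b}")
        pairs.append((a, b))
        provenance.append("literature")
        accepted += [a, b]

    attempts = 0
    while len(pairs) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SequenceDesignError(
                f"could not find {n} orthogonal loops with Hamming >= {m}"
            )
        a = "".join(rng.choice(bases, size=loop_len))
        b = revcomp_rna(a)
        if a == b:
            continue
        if violates_constraints(a, constraints) or violates_constraints(b, constraints):
            continue
        if _hamming(a, b) < m:
            continue
        if any(_hamming(a, s) < m or _hamming(b, s) < m for s in accepted):
            continue
        pairs.append((a, b))
        provenance.append("generated")
        accepted += [a, b]

    ens = KissingLoopEnsemble(
        pairs=pairs, provenance=provenance, min_hamming=m, loop_len=loop_len
    )
    problems = ens.validate(constraints)
    if problems:
        raise SequenceDesignError(f"generated ensemble invalid: {problems[:3]}")
    return ens


# ---------------------------------------------------------------------------
# Wobbles and sequence design
# ---------------------------------------------------------------------------


def apply_wobbles(
    strand: StrandModel,
    sequence: str,
    constraints: SequenceConstraints | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Insert G-U wobbles at fixed intervals along every stem duplex.

    Within each stem block, every ``wobble_interval``-th pair (1-based,
    counted from the block's 5'-most pair) becomes G (on the
    first-traversed strand) and U (on the partner).  Kissing-loop
    pairing regions are never wobbled.  Returns the new sequence and the
    wobbled (position5, position3) pairs.
    """
    constraints = constraints or SequenceConstraints()
    seq = list(sequence)
    wobbles: list[tuple[int, int]] = []
    for side5, side3 in strand.stem_blocks():
        for k in range(constraints.wobble_interval, len(side5) + 1, constraints.wobble_interval):
            i, j = side5[k - 1], side3[k - 1]
            seq[i] = "G"
            seq[j] = "U"
            wobbles.append((i, j))
    return "".join(seq), wobbles


@dataclass
class DesignResult:
    sequence: str
    wobbles: list[tuple[int, int]]
    kl_assignments: list[tuple[str, str]]  # ensemble pair used per KL block


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _check_design(strand: StrandModel, seq: str, constraints: SequenceConstraints) -> None:
    """Independent post-hoc validation of a designed sequence."""
    v = violates_constraints(seq, constraints)
    if v:
        raise SequenceDesignError(f"forbidden patterns remain: {v[:3]}")
    kl_positions = {p for a, b in strand.kl_blocks() for p in a + b}
    for i, j in strand.pairs():
        pair = (seq[i], seq[j])
        if i in kl_positions:
            if pair not in _WC:
                raise SequenceDesignError(f"kissing-loop pair {i}-{j} not Watson-Crick")
        elif pair not in _WC and pair not in _WOBBLE:
            raise SequenceDesignError(f"pair {i}-{j} is {pair}, neither WC nor G-U")


def design_sequence(
    strand: StrandModel,
    ensemble: KissingLoopEnsemble,
    constraints: SequenceConstraints | None = None,
    seed: int = 0,
    designer: str | None = "internal",
    stem_filler=None,
    unpaired_base: str = "A",
    max_restarts: int = 400,
) -> DesignResult:
    """Design the primary sequence for a strand model.

    Kissing-loop regions are set from the ensemble (one pair per
    region); stems are filled with GC-bounded random complementary bases
    (or by ``stem_filler(length, rng) -> str`` when
    ``designer='external-adapter'``), wobbled, and the whole sequence is
    resampled until no forbidden pattern remains.  The first base is
    forced to G (T7 transcription requirement).  Deterministic per seed.
    """
    constraints = constraints or SequenceConstraints()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))

    kl_blocks = strand.kl_blocks()
    if len(ensemble.pairs) < len(kl_blocks):
        raise SequenceDesignError(
            f"ensemble has {len(ensemble.pairs)} pairs; design needs {len(kl_blocks)}"
        )
    if designer == "external-adapter" and stem_filler is None:
        raise ValueError("external-adapter designer requires a stem_filler callable")

    seq = [unpaired_base] * strand.length

    # kissing loops: region A (5'-most) gets loop_a; complementarity then
    # makes region B read loop_b in 5'->3' order
    assignments: list[tuple[str, str]] = []
    for (side5, side3), pair in zip(kl_blocks, ensemble.pairs):
        loop_a, loop_b = pair
        if len(side5) != len(loop_a):
            raise SequenceDesignError(
                f"kissing-loop region length {len(side5)} != loop length {len(loop_a)}"
            )
        for p, b in zip(side5, loop_a):
            seq[p] = b
            seq[strand.pairing[p]] = _RNA_COMP[b]
        assignments.append(pair)

    stem_blocks = strand.stem_blocks()

    def sample_stem(length: int) -> str:
        if stem_filler is not None:
            return stem_filler(length, rng)
        for _ in range(1000):
            draft = "".join(rng.choice(bases, size=length))
            if length < 4:
                return draft
            gc = sum(1 for b in draft if b in "GC") / length
            if constraints.gc_min <= gc <= constraints.gc_max:
                return draft
        return draft  # fall back to the last draft

    def fill_stem(block: tuple[list[int], list[int]]) -> None:
        side5, side3 = block
        draft = sample_stem(len(side5))
        for p, b in zip(side5, draft):
            seq[p] = b
            seq[strand.pairing[p]] = _RNA_COMP[b]

    for block in stem_blocks:
        fill_stem(block)

    wobbles: list[tuple[int, int]] = []

    def rewobble() -> None:
        nonlocal wobbles
        joined, wobbles = apply_wobbles(strand, "".join(seq), constraints)
        seq[:] = list(joined)

    def force_t7_start() -> None:
        if strand.length == 0:
            return
        seq[0] = "G"
        if 0 in strand.pairing:
            seq[strand.pairing[0]] = "C"

    rewobble()
    force_t7_start()

    pos_to_stem: dict[int, int] = {}
    for bi, (side5, side3) in enumerate(stem_blocks):
        for p in side5 + side3:
            pos_to_stem[p] = bi
    kl_positions = {p for a, b in kl_blocks for p in a + b}
    mutable_unpaired = set(strand.unpaired_positions())

    for _ in range(max_restarts):
        violations = violates_constraints("".join(seq), constraints)
        if not violations:
            break
        touched_stems: set[int] = set()
        for pattern, start in violations:
            for p in range(start, min(start + len(pattern), strand.length)):
                if p in pos_to_stem:
                    touched_stems.add(pos_to_stem[p])
                elif p in mutable_unpaired:
                    cur = seq[p]
                    choices = [b for b in "ACGU" if b != cur]
                    seq[p] = choices[int(rng.integers(len(choices)))]
        for bi in touched_stems:
            fill_stem(stem_blocks[bi])
        if touched_stems:
            rewobble()
        force_t7_start()
    else:
        raise SequenceDesignError(
            f"constraint satisfaction failed after {max_restarts} restarts"
        )

    final = "".join(seq)
    _check_design(strand, final, constraints)
    return DesignResult(sequence=final, wobbles=wobbles, kl_assignments=assignments)


# ---------------------------------------------------------------------------
# DNA template
# ---------------------------------------------------------------------------


@dataclass
class DnaTemplate:
    """T7 transcription template: cap + promoter + body + tail, plus primers."""

    template: str
    cap: str
    promoter: str
    body: str
    tail: str
    forward_primer: str
    reverse_primer: str
    wobble_positions: list[tuple[int, int]] = field(default_factory=list)


def build_dna_template(
    rna: str,
    tail_seed: int = 0,
    target_tm: float = 58.0,
    constraints: SequenceConstraints | None = None,
    wobble_positions: list[tuple[int, int]] | None = None,
    max_reverse_len: int = 40,
) -> DnaTemplate:
    """DNA template and PCR primers for an RNA design.

    The template is ``GAC`` + the T7 promoter + the DNA-alphabet body +
    a seeded 15 nt tail that passes the forbidden-pattern rules.  The
    forward primer is cap+promoter; the reverse primer is the reverse
    complement of the template's 3' end, extended beyond 15 nt until its
    Wallace-rule Tm reaches ``target_tm``.
    """
    if not rna or rna[0] != "G":
        raise SequenceDesignError("T7 requires 5' G")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    constraints = constraints or SequenceConstraints()
    body = rna.replace("U", "T")
    rng = np.random.default_rng(tail_seed)
    bases = np.array(list("ACGT"))
    prefix = CAP + T7_PROMOTER + body
    for _ in range(10000):
        tail = "".join(rng.choice(bases, size=TAIL_LENGTH))
        if violates_constraints(tail, constraints, alphabet="DNA"):
            continue
        # also guard the junction between body and tail
        window = (prefix + tail)[-(TAIL_LENGTH + constraints.class_run) :]
        if not violates_constraints(window, constraints, alphabet="DNA"):
            break
    else:
        raise SequenceDesignError("could not generate a clean 15 nt tail")

    template = prefix + tail
    forward = CAP + T7_PROMOTER
    k = TAIL_LENGTH
    reverse = revcomp_dna(template[-k:])
    while wallace_tm(reverse) < target_tm and k < min(max_reverse_len, len(template)):
        k += 1
        reverse = revcomp_dna(template[-k:])
    return DnaTemplate(
        template=template,
        cap=CAP,
        promoter=T7_PROMOTER,
        body=body,
        tail=tail,
        forward_primer=forward,
        reverse_primer=reverse,
        wobble_positions=list(wobble_positions or []),
    )
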