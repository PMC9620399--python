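"""Strand-level structure: pairing map, dot-bracket, and the snac format.

The strand is an ordered list of domains with a position-level pairing
map (an involution).  Watson-Crick stem pairs nest and are written with
``()``; kissing-loop pairs cross them and are written with pseudoknot
bracket layers (``[]``, ``{}``, ``<>``, ``Aa``, ``Bb``, ...), assigned
by greedy first-fit interval coloring.

The snac ("Simple Nucleic Acid Code") dialect written here is a
line-oriented, versioned text format:

    # snac 1
    name <label>
    length <N>
    <sequence line>
    <structure line>
    <x> <y> <z>        (one line per nucleotide, nm)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EmbeddedDesign

__all__ = [
    "StrandModel",
    "SnacDocument",
    "StructureError",
    "build_strand_model",
    "strand_model_from_structure",
    "to_dotbracket",
    "parse_dotbracket",
    "write_snac",
    "read_snac",
    "write_fasta",
    "write_vienna",
    "BRACKET_ALPHABET",
]

BRACKET_ALPHABET: list[tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + i), chr(ord("a") + i)) for i in range(26)
]


class StructureError(ValueError):
    """Raised for inconsistent pairing maps or malformed snac files."""


@dataclass
class StrandModel:
    """Ordered domains plus a position-level pairing involution.

    ``domains`` entries are ``(kind, length, partner_domain_or_None,
    edge_or_None)``; ``pairing`` maps position -> position with no fixed
    points.
    """

    domains: list[tuple[str, int, int | None, int | None]]
    pairing: dict[int, int]
    length: int

    def __post_init__(self) -> None:
        for i, j in self.pairing.items():
            if i == j:
                raise StructureError(f"self-paired position {i}")
            if self.pairing.get(j) != i:
                raise StructureError(f"pairing map is not an involution at {i}<->{j}")
            if not (0 <= i < self.length and 0 <= j < self.length):
                raise StructureError("pairing position out of range")

    # -- derived views -----------------------------------------------------

    def pairs(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, j in self.pairing.items() if i < j)

    def pair_layers(self) -> list[list[tuple[int, int]]]:
        """Greedy first-fit assignment of pairs to non-crossing layers."""
        layers: list[list[tuple[int, int]]] = []
        for pair in self.pairs():
            for layer in layers:
                if not any(_cross(pair, q) for q in layer):
                    layer.append(pair)
                    break
            else:
                layers.append([pair])
        return layers

    def stem_blocks(self) -> list[tuple[list[int], list[int]]]:
        """Nested (layer-0) helical runs as (5'-side, 3'-side) position lists.

        Each block is a maximal run of stacked pairs (i, j), (i+1, j-1),
        ...; the 5' side ascends.  Wobble insertion counts pairs from the
        start of each block.
        """
        layers = self.pair_layers()
        return _blocks(layers[0]) if layers else []

    def kl_blocks(self) -> list[tuple[list[int], list[int]]]:
        """Kissing-loop pairing regions (all layers beyond the first)."""
        out = []
        for layer in self.pair_layers()[1:]:
            out.extend(_blocks(layer))
        return out

    def unpaired_positions(self) -> list[int]:
        return [i for i in range(self.length) if i not in self.pairing]


def _cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def _blocks(layer: list[tuple[int, int]]) -> list[tuple[list[int], list[int]]]:
    layer = sorted(layer)
    blocks: list[tuple[list[int], list[int]]] = []
    for i, j in layer:
        if blocks and blocks[-1][0][-1] == i - 1 and blocks[-1][1][-1] == j + 1:
            blocks[-1][0].append(i)
            blocks[-1][1].append(j)
        else:
            blocks.append(([i], [j]))
    return blocks


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def build_strand_model(embedded: EmbeddedDesign) -> StrandModel:
    """Strand model of an embedded design.

    The pairing map is derived from helix-row sharing: every base-pair
    row of every edge hosts exactly two nucleotides (one per strand of
    the duplex), which are partners.  Tree edges produce nested stem
    pairs; non-tree edges produce hairpin stems plus the crossing
    kissing-loop pairs between the two loop regions.
    """
    pairing: dict[int, int] = {}
    row_owner: dict[tuple[int, int], int] = {}
    pos = 0
    domain_ranges: list[tuple[int, int]] = []
    for d in embedded.domains:
        start = pos
        if d.kind == "linker":
            pos += d.length
        elif d.kind == "kl_loop":
            pos += d.flank
            for r in d.rows:
                key = (d.edge, r)
                if key in row_owner:
                    pairing[row_owner[key]] = pos
                    pairing[pos] = row_owner[key]
                else:
                    row_owner[key] = pos
                pos += 1
            pos += d.flank
        else:
            for r in d.rows:
                key = (d.edge, r)
                if key in row_owner:
                    pairing[row_owner[key]] = pos
                    pairing[pos] = row_owner[key]
                else:
                    row_owner[key] = pos
                pos += 1
        domain_ranges.append((start, pos))

    unmatched = [k for k, v in row_owner.items() if v not in pairing]
    if unmatched:
        raise StructureError(f"unpaired helix rows: {unmatched[:5]}")

    # partner domain ids from the pairing of each domain's first paired base
    partners: list[int | None] = []
    for di, d in enumerate(embedded.domains):
        rng = domain_ranges[di]
        partner = None
        for p in range(*rng):
            if p in pairing:
                q = pairing[p]
                for dj, rng2 in enumerate(domain_ranges):
                    if rng2[0] <= q < rng2[1] and dj != di:
                        partner = dj
                        break
                break
        partners.append(partner)

    domains = [
        (d.kind, d.length, partners[di], d.edge) for di, d in enumerate(embedded.domains)
    ]
    return StrandModel(domains=domains, pairing=pairing, length=pos)


def strand_model_from_structure(structure: str) -> StrandModel:
    """Rebuild a strand model from a layered dot-bracket string.

    Layer-0 runs become stem domains, higher layers kissing-loop pairing
    regions, and unpaired positions linkers — enough for the sequence
    designer to operate on a bare snac file.
    """
    pairing = parse_dotbracket(structure)
    model = StrandModel(domains=[], pairing=pairing, length=len(structure))
    kinds = ["linker"] * len(structure)
    for side5, side3 in model.stem_blocks():
        for p in side5:
            kinds[p] = "stem5"
        for p in side3:
            kinds[p] = "stem3"
    for side5, side3 in model.kl_blocks():
        for p in side5 + side3:
            kinds[p] = "kl_loop"
    domains: list[tuple[str, int, int | None, int | None]] = []
    for i, kind in enumerate(kinds):
        if domains and domains[-1][0] == kind:
            k, ln, pr, ed = domains[-1]
            domains[-1] = (k, ln + 1, pr, ed)
        else:
            domains.append((kind, 1, None, None))
    model.domains = domains
    return model


# ---------------------------------------------------------------------------
# Dot-bracket
# ---------------------------------------------------------------------------


def to_dotbracket(strand: StrandModel) -> str:
    """Layered dot-bracket string of the pairing map."""
    layers = strand.pair_layers()
    if len(layers) > len(BRACKET_ALPHABET):
        raise StructureError(
            f"structure needs {len(layers)} pseudoknot layers; alphabet has "
            f"{len(BRACKET_ALPHABET)}"
        )
    chars = ["."] * strand.length
    for layer, (open_c, close_c) in zip(layers, BRACKET_ALPHABET):
        for i, j in layer:
            chars[i] = open_c
            chars[j] = close_c
    return "".join(chars)


def parse_dotbracket(structure: str) -> dict[int, int]:
    """Pairing map from a layered dot-bracket string (strict)."""
    openers = {o: k for k, (o, _) in enumerate(BRACKET_ALPHABET)}
    closers = {c: k for k, (_, c) in enumerate(BRACKET_ALPHABET)}
    stacks: dict[int, list[int]] = {}
    pairing: dict[int, int] = {}
    for pos, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in openers:
            stacks.setdefault(openers[ch], []).append(pos)
        elif ch in closers:
            stack = stacks.get(closers[ch], [])
            if not stack:
                raise StructureError(f"unbalanced {ch!r} at position {pos}")
            i = stack.pop()
            pairing[i] = pos
            pairing[pos] = i
        else:
            raise StructureError(f"unknown structure character {ch!r} at {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced {BRACKET_ALPHABET[layer][0]!r} at position {stack[-1]}"
            )
    return pairing


# ---------------------------------------------------------------------------
# snac I/O
# ---------------------------------------------------------------------------

SNAC_VERSION = 1


@dataclass
class SnacDocument:
    """The pipeline's interchange object: sequence + structure + coordinates."""

    name: str
    sequence: str
    structure: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.sequence)
        if len(self.structure) != n:
            raise StructureError(
                f"length mismatch: sequence {n} vs structure {len(self.structure)}"
            )
        if self.coordinates.shape != (n, 3):
            raise StructureError(
                f"length mismatch: sequence {n} vs coordinates {self.coordinates.shape}"
            )
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise StructureError(f"invalid sequence characters: {sorted(bad)}")
        parse_dotbracket(self.structure)  # raises if unbalanced

    def pairing(self) -> dict[int, int]:
        return parse_dotbracket(self.structure)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnacDocument):
            return NotImplemented
        return (
            self.name == other.name
            and self.sequence == other.sequence
            and self.structure == other.structure
            and np.allclose(self.coordinates, other.coordinates, atol=1e-6)
        )


def write_snac(doc: SnacDocument, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# snac {SNAC_VERSION}\n")
        fh.write(f"name {doc.name}\n")
        fh.write(f"length {len(doc.sequence)}\n")
        fh.write(doc.sequence + "\n")
        fh.write(doc.structure + "\n")
        for x, y, z in doc.coordinates:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_snac(path: str) -> SnacDocument:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 5:
        raise StructureError("snac file truncated")
    if not lines[0].startswith("# snac"):
        raise StructureError("line 1: missing snac header")
    if not lines[1].startswith("name "):
        raise StructureError("line 2: missing name record")
    name = lines[1][5:].strip()
    if not lines[2].startswith("length "):
        raise StructureError("line 3: missing length record")
    try:
        n = int(lines[2].split()[1])
    except (IndexError, ValueError) as exc:
        raise StructureError("line 3: bad length record") from exc
    sequence = lines[3].strip()
    structure = lines[4].strip()
    if len(sequence) != n:
        raise StructureError(f"line 4: sequence length {len(sequence)} != declared {n}")
    if len(structure) != n:
        raise StructureError(f"line 5: structure length {len(structure)} != declared {n}")
    coords = []
    for lineno, ln in enumerate(lines[5 : 5 + n], start=6):
        parts = ln.split()
        if len(parts) != 3:
            raise StructureError(f"line {lineno}: expected 3 coordinates")
        try:
            coords.append([float(p) for p in parts])
        except ValueError as exc:
            raise StructureError(f"line {lineno}: bad coordinate value") from exc
    if len(coords) != n:
        raise StructureError(f"expected {n} coordinate lines, found {len(coords)}")
    return SnacDocument(name=name, sequence=sequence, structure=structure, coordinates=np.array(coords))


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vienna(doc: SnacDocument, path: str) -> None:
    """Plain dot-bracket file: name line, sequence line, structure line."""
    with open(path, "w") as fh:
        fh.write(f">{doc.name}\n{doc.sequence}\n{doc.structure}\n")
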