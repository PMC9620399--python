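"""oxDNA export (the snac2ox stage).

Writes the classic two-file oxDNA input: a topology file (strand
connectivity, one line per nucleotide) and a configuration file
(positions and orientation frames).  Per oxDNA convention nucleotides
are listed 3'->5'; snac documents are 5'->3', so the converter reverses
the order and remaps neighbor indices.  Lengths are converted from nm
to simulation units (0.8518 nm per unit).  Velocities are
zero-initialized; relaxation is the simulator's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import SnacDocument

__all__ = [
    "OxModel",
    "OxExportError",
    "NM_PER_OX_UNIT",
    "snac_to_ox",
    "write_ox_files",
    "read_ox_files",
]

NM_PER_OX_UNIT = 0.8518


class OxExportError(ValueError):
    pass


@dataclass
class OxModel:
    """oxDNA model in file order (3'->5' along the single strand).

    ``neighbor3``/``neighbor5`` are indices into the file order, -1 at
    chain ends.  ``a1`` points from the backbone toward the paired base
    (or toward the local helix axis for unpaired bases); ``a3`` is the
    base normal, orthogonal to ``a1``.  Positions and box are in oxDNA
    simulation units.
    """

    sequence: str
    strand_ids: np.ndarray
    neighbor3: np.ndarray
    neighbor5: np.ndarray
    positions: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    velocities: np.ndarray
    angular_velocities: np.ndarray
    box: np.ndarray

    @property
    def n_nucleotides(self) -> int:
        return len(self.sequence)

    def validate(self) -> list[str]:
        problems = []
        n = self.n_nucleotides
        for name, vecs in (("a1", self.a1), ("a3", self.a3)):
            norms = np.linalg.norm(vecs, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                problems.append(f"{name} vectors not unit length")
        dots = np.abs(np.sum(self.a1 * self.a3, axis=1))
        if np.any(dots > 1e-6):
            problems.append("a1/a3 not orthogonal")
        if np.any(self.positions < 0) or np.any(self.positions > self.box):
            problems.append("positions outside box")
        # single open chain per strand
        heads = [i for i in range(n) if self.neighbor3[i] == -1]
        if len(heads) != len(set(self.strand_ids)):
            problems.append("wrong number of chain heads")
        seen = 0
        for h in heads:
            i = h
            while i != -1:
                seen += 1
                i = int(self.neighbor5[i])
                if seen > n:
                    problems.append("neighbor graph has a cycle")
                    return problems
        if seen != n:
            problems.append("neighbor graph does not cover all nucleotides")
        return problems


def _orthonormal_frames(
    coords: np.ndarray, pairing: dict[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """a1 (toward paired base) and a3 (along local strand axis), 5'->3' order."""
    n = len(coords)
    a1 = np.zeros((n, 3))
    a3 = np.zeros((n, 3))
    # local tangent from neighbors along the strand
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n - 1, i + 1)
        t = coords[hi] - coords[lo]
        tn = np.linalg.norm(t)
        a3[i] = t / tn if tn > 1e-9 else np.array([0.0, 0.0, 1.0])
    for i in range(n):
        if i in pairing:
            v = coords[pairing[i]] - coords[i]
        else:
            # unpaired: average the paired neighbors' directions, else any
            v = np.zeros(3)
            for j in (i - 1, i + 1):
                if 0 <= j < n and j in pairing:
                    v = v + (coords[pairing[j]] - coords[j])
            if np.linalg.norm(v) < 1e-9:
                v = np.array([1.0, 0.0, 0.0])
        # Gram-Schmidt against a3 so the frame is exactly orthonormal
        v = v - float(np.dot(v, a3[i])) * a3[i]
        vn = np.linalg.norm(v)
        if vn < 1e-9:
            probe = np.array([1.0, 0.0, 0.0])
            if abs(float(np.dot(probe, a3[i]))) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            v = probe - float(np.dot(probe, a3[i])) * a3[i]
            vn = np.linalg.norm(v)
        a1[i] = v / vn
    return a1, a3


def snac_to_ox(
    doc: SnacDocument,
    pairing: dict[int, int] | None = None,
    box_padding: float = 5.0,
) -> OxModel:
    """Convert a fully sequenced snac document into an oxDNA model.

    ``box_padding`` (nm) is added on every side of the bounding box.
    Raises :class:`OxExportError` if the sequence still contains N
    placeholders.
    """
    if "N" in doc.sequence:
        raise OxExportError("sequence contains N placeholders; design it first")
    if pairing is None:
        pairing = doc.pairing()
    coords = np.asarray(doc.coordinates, dtype=float)
    n = len(doc.sequence)

    a1, a3 = _orthonormal_frames(coords, pairing)

    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    box_nm = span + 2.0 * box_padding
    shifted = coords - lo + box_padding

    # reverse 5'->3' (snac) into 3'->5' (oxDNA file order)
    order = np.arange(n)[::-1]
    seq = doc.sequence[::-1]
    positions = shifted[order] / NM_PER_OX_UNIT
    a1r = a1[order]
    a3r = a3[order]
    neighbor3 = np.arange(n) - 1
    neighbor5 = np.arange(n) + 1
    neighbor5[-1] = -1

    return OxModel(
        sequence=seq,
        strand_ids=np.ones(n, dtype=int),
        neighbor3=neighbor3,
        neighbor5=neighbor5,
        positions=positions,
        a1=a1r,
        a3=a3r,
        velocities=np.zeros((n, 3)),
        angular_velocities=np.zeros((n, 3)),
        box=box_nm / NM_PER_OX_UNIT,
    )


def write_ox_files(model: OxModel, topology_path: str, configuration_path: str) -> None:
    """Write topology (.top) and configuration (.conf) files.

    Fixed-point 8-decimal floats keep the output byte-reproducible.
    """
    problems = model.validate()
    if problems:
        raise OxExportError(f"invalid model: {problems}")
    n = model.n_nucleotides
    with open(topology_path, "w") as fh:
        fh.write(f"{n} {len(set(model.strand_ids.tolist()))}\n")
        for i in range(n):
            fh.write(
                f"{model.strand_ids[i]} {model.sequence[i]} "
                f"{model.neighbor3[i]} {model.neighbor5[i]}\n"
            )
    with open(configuration_path, "w") as fh:
        fh.write("t = 0\n")
        fh.write(f"b = {model.box[0]:.8f} {model.box[1]:.8f} {model.box[2]:.8f}\n")
        fh.write("E = 0 0 0\n")
        for i in range(n):
            row = np.concatenate(
                [
                    model.positions[i],
                    model.a1[i],
                    model.a3[i],
                    model.velocities[i],
                    model.angular_velocities[i],
                ]
            )
            fh.write(" ".join(f"{x:.8f}" for x in row) + "\n")


def read_ox_files(topology_path: str, configuration_path: str) -> OxModel:
    """Parse files written by :func:`write_ox_files` (round-trip support)."""
    with open(topology_path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        strand_ids, seq_chars, n3, n5 = [], [], [], []
        for _ in range(n):
            parts = fh.readline().split()
            strand_ids.append(int(parts[0]))
            seq_chars.append(parts[1])
            n3.append(int(parts[2]))
            n5.append(int(parts[3]))
    with open(configuration_path) as fh:
        fh.readline()  # t = 0
        box = np.array([float(x) for x in fh.readline().split()[2:5]])
        fh.readline()  # E line
        rows = [np.array([float(x) for x in fh.readline().split()]) for _ in range(n)]
    rows_arr = np.array(rows)
    return OxModel(
        sequence="".join(seq_chars),
        strand_ids=np.array(strand_ids),
        neighbor3=np.array(n3),
        neighbor5=np.array(n5),
        positions=rows_arr[:, 0:3],
        a1=rows_arr[:, 3:6],
        a3=rows_arr[:, 6:9],
        velocities=rows_arr[:, 9:12],
        angular_velocities=rows_arr[:, 12:15],
        box=box,
    )
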