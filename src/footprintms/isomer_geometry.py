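"""Peptide-bond ω dihedral and cis/trans classification.

The ω angle is the CA(i)–C(i)–N(i+1)–CA(i+1) dihedral of the peptide bond.
Nearly all peptide bonds sit near ω = 180° (trans); bonds preceding
proline can also adopt ω ≈ 0° (cis), and prolyl isomerases interconvert
the two — the structural switch this package's footprinting comparison is
designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_HALFWIDTH_DEG = 30.0


def omega_angle(
    ca_i: Sequence[float],
    c_i: Sequence[float],
    n_next: Sequence[float],
    ca_next: Sequence[float],
) -> float:
    """Signed dihedral (degrees, in (-180, 180]) of the CA–C–N–CA frame."""
    p = [np.asarray(x, dtype=float) for x in (ca_i, c_i, n_next, ca_next)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if (
        norm_b2 < 1e-9
        or np.linalg.norm(n1) < 1e-9
        or np.linalg.norm(n2) < 1e-9
    ):
        raise ValueError("degenerate geometry: collinear or coincident atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def classify_isomer(
    omega_deg: float,
    cis_halfwidth_deg: float = DEFAULT_HALFWIDTH_DEG,
    trans_halfwidth_deg: float = DEFAULT_HALFWIDTH_DEG,
) -> str:
    """``cis`` if |ω| ≤ cis halfwidth, ``trans`` if |180 − |ω|| ≤ trans
    halfwidth, else ``twisted``."""
    if abs(omega_deg) <= cis_halfwidth_deg:
        return "cis"
    if abs(180.0 - abs(omega_deg)) <= trans_halfwidth_deg:
        return "trans"
    return "twisted"


@dataclass(frozen=True)
class OmegaClassification:
    residue: int
    next_residue: int
    omega_deg: float
    label: str


def omega_table(
    pdb_path: str,
    chain: str | None = None,
    cis_halfwidth_deg: float = DEFAULT_HALFWIDTH_DEG,
    trans_halfwidth_deg: float = DEFAULT_HALFWIDTH_DEG,
) -> list[OmegaClassification]:
    """ω angle and cis/trans class for every consecutive residue pair with
    complete backbone atoms in a PDB file (ATOM records only)."""
    import gemmi

    structure = gemmi.read_structure(pdb_path)
    structure.setup_entities()
    out = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            residues = [r for r in ch if r.het_flag == "A"]
            for prev, curr in zip(residues, residues[1:]):
                atoms = {}
                for name, res in (("CA", prev), ("C", prev), ("N", curr), ("CA2", curr)):
                    atom = res.find_atom(name.rstrip("2"), "*")
                    if atom is None:
                        atoms = None
                        break
                    atoms[name] = (atom.pos.x, atom.pos.y, atom.pos.z)
                if not atoms:
                    continue
                omega = omega_angle(
                    atoms["CA"], atoms["C"], atoms["N"], atoms["CA2"]
                )
                out.append(
                    OmegaClassification(
                        residue=prev.seqid.num,
                        next_residue=curr.seqid.num,
                        omega_deg=omega,
                        label=classify_isomer(
                            omega, cis_halfwidth_deg, trans_halfwidth_deg
                        ),
                    )
                )
        break  # first model only
    return out
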