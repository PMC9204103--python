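"""Peptide-mass-fingerprint matching of theoretical peptides to MS1 peaks.

MALDI-TOF of an in-gel digest gives one survey spectrum whose peaks are, to
first order, singly protonated tryptic peptides.  Because the protein is
known, identification reduces to matching each observed m/z against the
enumerated candidate peptide forms (including biotinylated ones) within a
ppm tolerance.  Footprinting only needs presence/absence calls, so each
peak is assigned its single best candidate; the full many-to-many match
list is retained for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .digest import PeptideForm, ProteinRecord
from .io_formats import PeakList
from .masses import mz_from_mass

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 50.0  # MALDI-TOF reflector-mode MS1


@dataclass(frozen=True)
class PeptideMatch:
    peptide: PeptideForm
    theoretical_mz: float
    observed_mz: float
    error_ppm: float
    charge: int


@dataclass(frozen=True)
class PmfResult:
    """Best assignment per peak plus the full candidate match list."""

    assignments: tuple[PeptideMatch, ...]
    all_matches: tuple[PeptideMatch, ...]

    def to_records(self) -> list[dict]:
        return [
            {
                "protein_id": m.peptide.protein_id,
                "start": m.peptide.start,
                "end": m.peptide.end,
                "sequence": m.peptide.sequence,
                "mods": ";".join(f"{p}:{n}" for p, n in m.peptide.mod_names),
                "missed_cleavages": m.peptide.missed_cleavages,
                "theoretical_mz": m.theoretical_mz,
                "observed_mz": m.observed_mz,
                "error_ppm": m.error_ppm,
                "charge": m.charge,
            }
            for m in self.assignments
        ]


def _tie_key(match: PeptideMatch):
    # total order: |ppm error|, fewer mods, fewer missed cleavages, sequence
    return (
        abs(match.error_ppm),
        len(match.peptide.mods),
        match.peptide.missed_cleavages,
        match.peptide.sequence,
        match.peptide.start,
        match.charge,
    )


def match_pmf(
    candidates: Sequence[PeptideForm],
    peaks: PeakList,
    tol_ppm: float = DEFAULT_TOL_PPM,
    charge_states: Sequence[int] = (1,),
    fixed_carbamidomethyl: bool = True,
) -> PmfResult:
    """Match candidate peptide forms against an MS1 peak list.

    Every (peak, candidate, charge) pair within ``tol_ppm`` enters the
    diagnostic list; each peak is then assigned its best candidate by
    absolute mass error with deterministic tie-breaking.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(peaks) == 0:
        logger.warning("empty peak list: no matches possible")
        return PmfResult(assignments=(), all_matches=())

    theoretical = sorted(
        (
            (mz_from_mass(c.mass(fixed_carbamidomethyl), z), c, z)
            for c in candidates
            for z in charge_states
        ),
        key=lambda t: t[0],
    )
    theo_mz = [t[0] for t in theoretical]

    import bisect

    all_matches: list[PeptideMatch] = []
    assignments: list[PeptideMatch] = []
    for observed, _intensity in peaks.peaks:
        half_width = observed * tol_ppm * 1e-6
        lo = bisect.bisect_left(theo_mz, observed - half_width)
        hi = bisect.bisect_right(theo_mz, observed + half_width)
        peak_matches = []
        for mz, candidate, charge in theoretical[lo:hi]:
            error_ppm = (observed - mz) / mz * 1e6
            if abs(error_ppm) <= tol_ppm:
                peak_matches.append(
                    PeptideMatch(candidate, mz, observed, error_ppm, charge)
                )
        all_matches.extend(peak_matches)
        if peak_matches:
            assignments.append(min(peak_matches, key=_tie_key))
    return PmfResult(assignments=tuple(assignments), all_matches=tuple(all_matches))


def sequence_coverage(
    matches: Sequence[PeptideMatch], protein: ProteinRecord
) -> float:
    """Fraction of protein residues covered by at least one matched peptide."""
    covered: set[int] = set()
    for match in matches:
        if match.peptide.protein_id != protein.id:
            continue
        covered.update(range(match.peptide.start, match.peptide.end + 1))
    return len(covered) / len(protein)
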