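"""Differential surface-accessibility mapping.

Each conformational state yields a set of confidently biotinylated lysines
(an accessibility map).  Comparing two states gives the footprinting
result proper: lysines accessible only in one conformer mark regions that
fold away in the other.  Positions are annotated against a domain table so
that, e.g., state-specific lysines can be read as exposure of the BH3-like
region or protection near the kinase domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digest import ProteinRecord
from .io_formats import PrintedPeptide
from .pmf_match import PeptideMatch
from .site_localization import (
    CONFIDENT_DELTA_ASCORE,
    SiteLocalizationResult,
)


@dataclass(frozen=True)
class SiteEvidence:
    spectrum_count: int
    best_delta_ascore: float
    peptides: tuple[str, ...]


@dataclass(frozen=True)
class AccessibilityMap:
    """Per-state confidently modified lysine positions with evidence."""

    state_label: str
    protein_id: str
    modified: Mapping[int, SiteEvidence]

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(self.modified)

    @classmethod
    def from_positions(
        cls, state_label: str, protein_id: str, positions: Iterable[int]
    ) -> "AccessibilityMap":
        """Build a map from bare position calls (e.g. a published list)."""
        return cls(
            state_label,
            protein_id,
            {
                int(p): SiteEvidence(1, float("inf"), ())
                for p in positions
            },
        )


def build_accessibility_map(
    state_label: str,
    matches: Sequence[PeptideMatch],
    localizations: Sequence[SiteLocalizationResult],
    min_delta_ascore: float = CONFIDENT_DELTA_ASCORE,
    min_witnesses: int = 1,
    protein: ProteinRecord | None = None,
) -> AccessibilityMap:
    """Call a lysine modified when enough spectra localize the label there.

    A localization counts as a witness when its delta-Ascore meets
    ``min_delta_ascore``; peptides with a single candidate site are
    inherently unambiguous and always count.
    """
    protein_ids = {m.peptide.protein_id for m in matches} | {
        loc.peptide.protein_id for loc in localizations
    }
    if len(protein_ids) > 1:
        raise ValueError(f"evidence spans multiple proteins: {sorted(protein_ids)}")
    protein_id = protein_ids.pop() if protein_ids else (protein.id if protein else "")

    witnesses: dict[int, list[SiteLocalizationResult]] = {}
    for loc in localizations:
        if not (loc.unambiguous or loc.delta_ascore >= min_delta_ascore):
            continue
        witnesses.setdefault(loc.best_site, []).append(loc)

    modified = {}
    for site, locs in witnesses.items():
        if protein is not None and protein.residue(site) != "K":
            raise ValueError(f"called site {site} is not a lysine")
        if len(locs) >= min_witnesses:
            modified[site] = SiteEvidence(
                spectrum_count=len(locs),
                best_delta_ascore=max(l.delta_ascore for l in locs),
                peptides=tuple(sorted({l.peptide.sequence for l in locs})),
            )
    return AccessibilityMap(state_label, protein_id, modified)


@dataclass(frozen=True)
class DomainTable:
    """Named inclusive residue ranges; positions within ``flank_window`` of
    a boundary are labeled ``flank:<name>``."""

    entries: tuple[tuple[str, int, int], ...]
    flank_window: int = 5

    def __post_init__(self) -> None:
        for name, start, end in self.entries:
            if start > end:
                raise ValueError(f"domain {name!r}: start {start} > end {end}")

    def classify(self, position: int) -> str:
        for name, start, end in self.entries:
            if start <= position <= end:
                return name
        for name, start, end in self.entries:
            if (
                start - self.flank_window <= position < start
                or end < position <= end + self.flank_window
            ):
                return f"flank:{name}"
        return "unassigned"


#: Domain boundaries the source structure annotations print explicitly.
DEFAULT_DOMAINS = DomainTable(entries=(("BH3", 461, 474), ("KD", 2206, 2615)))


@dataclass(frozen=True)
class DifferentialReport:
    state_a: str
    state_b: str
    unique_to_a: frozenset[int]
    unique_to_b: frozenset[int]
    shared: frozenset[int]
    domain_labels: Mapping[int, str] = field(default_factory=dict)
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = (self.unique_to_a, self.unique_to_b, self.shared)
        if (
            self.unique_to_a & self.unique_to_b
            or self.unique_to_a & self.shared
            or self.unique_to_b & self.shared
        ):
            raise ValueError("unique/shared sets must be pairwise disjoint")

    @property
    def all_positions(self) -> frozenset[int]:
        return self.unique_to_a | self.unique_to_b | self.shared

    def classification(self, position: int) -> str:
        if position in self.unique_to_a:
            return f"unique_to_{self.state_a}"
        if position in self.unique_to_b:
            return f"unique_to_{self.state_b}"
        if position in self.shared:
            return "shared"
        raise KeyError(position)

    def to_records(self) -> list[dict]:
        records = []
        for position in sorted(self.all_positions):
            records.append(
                {
                    "residue": position,
                    "classification": self.classification(position),
                    "domain": self.domain_labels.get(position, ""),
                }
            )
        return records

    def to_dict(self) -> dict:
        return {
            "state_a": self.state_a,
            "state_b": self.state_b,
            "unique_to_a": sorted(self.unique_to_a),
            "unique_to_b": sorted(self.unique_to_b),
            "shared": sorted(self.shared),
            "domain_labels": {
                str(k): v for k, v in sorted(self.domain_labels.items())
            },
            "thresholds": dict(self.thresholds),
        }


def compare_states(
    map_a: AccessibilityMap, map_b: AccessibilityMap
) -> DifferentialReport:
    """Set-difference two accessibility maps of the same protein."""
    if map_a.protein_id and map_b.protein_id and map_a.protein_id != map_b.protein_id:
        raise ValueError(
            f"maps refer to different proteins: {map_a.protein_id!r} vs "
            f"{map_b.protein_id!r}"
        )
    a, b = map_a.positions, map_b.positions
    return DifferentialReport(
        state_a=map_a.state_label,
        state_b=map_b.state_label,
        unique_to_a=frozenset(a - b),
        unique_to_b=frozenset(b - a),
        shared=frozenset(a & b),
    )


def pool_maps(
    label: str, maps: Sequence[AccessibilityMap], rule: str = "union"
) -> AccessibilityMap:
    """Pool replicate/equivalent-state maps by union (default) or
    intersection of called positions."""
    if not maps:
        raise ValueError("no maps to pool")
    protein_ids = {m.protein_id for m in maps if m.protein_id}
    if len(protein_ids) > 1:
        raise ValueError("maps refer to different proteins")
    position_sets = [m.positions for m in maps]
    if rule == "union":
        pooled = frozenset().union(*position_sets)
    elif rule == "intersection":
        pooled = frozenset.intersection(*position_sets)
    else:
        raise ValueError(f"unknown pooling rule {rule!r}")
    merged = {}
    for position in pooled:
        evidences = [m.modified[position] for m in maps if position in m.modified]
        merged[position] = SiteEvidence(
            spectrum_count=sum(e.spectrum_count for e in evidences),
            best_delta_ascore=max(e.best_delta_ascore for e in evidences),
            peptides=tuple(sorted({p for e in evidences for p in e.peptides})),
        )
    return AccessibilityMap(label, protein_ids.pop() if protein_ids else "", merged)


def annotate_domains(
    report: DifferentialReport, domains: DomainTable = DEFAULT_DOMAINS
) -> DifferentialReport:
    """Attach a domain (or flank / unassigned) label to every position."""
    labels = {p: domains.classify(p) for p in report.all_positions}
    return DifferentialReport(
        state_a=report.state_a,
        state_b=report.state_b,
        unique_to_a=report.unique_to_a,
        unique_to_b=report.unique_to_b,
        shared=report.shared,
        domain_labels=labels,
        thresholds=report.thresholds,
    )


def domain_tally(report: DifferentialReport) -> dict[str, dict[str, int]]:
    """Per-domain counts of unique/shared calls."""
    tally: dict[str, dict[str, int]] = {}
    for position in report.all_positions:
        domain = report.domain_labels.get(position, "unassigned")
        cls = report.classification(position)
        tally.setdefault(domain, {})
        tally[domain][cls] = tally[domain].get(cls, 0) + 1
    return tally


def count_modified_in_printed_list(
    peptides: Sequence[PrintedPeptide],
) -> tuple[int, int]:
    """Count peptides, and peptides with >= 1 lowercase ``k`` (biotinylated
    lysine) in a published-table fixture.

    Lowercase ``c`` (carbamidomethyl cysteine) is tolerated; any other
    lowercase mark is unknown and rejected.
    """
    n_modified = 0
    for peptide in peptides:
        lower = [aa for aa in peptide.sequence if aa.islower()]
        unknown = sorted(set(lower) - {"k", "c"})
        if unknown:
            raise ValueError(
                f"unknown lowercase modification mark(s) {unknown} in "
                f"{peptide.sequence!r}"
            )
        if "k" in lower:
            n_modified += 1
    return len(peptides), n_modified
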