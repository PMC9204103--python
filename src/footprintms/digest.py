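"""Modification-aware in-silico trypsin digestion.

The footprinting readout hinges on one rule: trypsin cleaves C-terminal to
K/R (not before P), but a lysine carrying the biotin adduct is no longer a
substrate, so the cut site is *protected* and the two flanking tryptic
peptides fuse into one longer, label-bearing peptide.  Observation of the
fused peptide (and loss of the two short ones) is the mass-spectrometric
signature of a surface-accessible lysine.

Positions throughout are 1-based in *protein numbering*: the first residue
of a :class:`ProteinRecord` is labeled ``numbering_offset`` (default 1), so
constructs whose leading tag residue is position 1 can label the first
native residue as 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .masses import (
    BIOTIN_LC,
    InvalidModificationError,
    ModificationDef,
    peptide_mass,
    validate_sequence,
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with author-defined residue numbering."""

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        validate_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_position(self) -> int:
        return self.numbering_offset

    @property
    def last_position(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def residue(self, position: int) -> str:
        """Residue letter at a protein-numbering position."""
        index = position - self.numbering_offset
        if not 0 <= index < len(self.sequence):
            raise IndexError(
                f"position {position} outside protein {self.id!r} "
                f"({self.first_position}..{self.last_position})"
            )
        return self.sequence[index]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for inclusive protein-numbering range [start, end]."""
        if start > end:
            raise ValueError("start must be <= end")
        self.residue(start), self.residue(end)
        i = start - self.numbering_offset
        return self.sequence[i : i + (end - start + 1)]

    @property
    def lysine_positions(self) -> tuple[int, ...]:
        """All positions (protein numbering) carrying a lysine."""
        return tuple(
            i + self.numbering_offset
            for i, aa in enumerate(self.sequence)
            if aa == "K"
        )


@dataclass(frozen=True)
class PeptideForm:
    """A digestion product with coordinates, modification placements and
    missed-cleavage count.

    ``mods`` holds ``(position, ModificationDef)`` pairs with positions in
    protein numbering.  A cleavage-blocking modification never sits on the
    peptide's C-terminal residue, and blocked internal sites do not count
    toward ``missed_cleavages``.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    mods: tuple[tuple[int, ModificationDef], ...] = field(default_factory=tuple)
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"[{self.start}, {self.end}]"
            )
        mods = tuple(sorted(self.mods, key=lambda m: (m[0], m[1].name)))
        for position, mod in mods:
            if not self.start <= position <= self.end:
                raise InvalidModificationError(
                    f"modification position {position} outside peptide span "
                    f"[{self.start}, {self.end}]"
                )
            residue = self.sequence[position - self.start]
            if residue not in mod.targets:
                raise InvalidModificationError(
                    f"modification {mod.name!r} cannot sit on residue "
                    f"{residue!r} at position {position}"
                )
            if mod.blocks_cleavage and position == self.end:
                raise InvalidModificationError(
                    f"cleavage-blocking modification {mod.name!r} cannot sit "
                    f"on the C-terminal residue (position {position})"
                )
        object.__setattr__(self, "mods", mods)

    @property
    def mod_names(self) -> tuple[tuple[int, str], ...]:
        return tuple((pos, mod.name) for pos, mod in self.mods)

    @property
    def local_mods(self) -> tuple[tuple[int, ModificationDef], ...]:
        """Mods with positions converted to 1-based peptide coordinates."""
        return tuple((pos - self.start + 1, mod) for pos, mod in self.mods)

    def key(self) -> tuple:
        """Identity for deduplication: span plus modification multiset."""
        return (self.protein_id, self.start, self.end, self.mod_names)

    def mass(self, fixed_carbamidomethyl: bool = True) -> float:
        """Neutral monoisotopic mass, Da (cysteines alkylated by default)."""
        return peptide_mass(
            self.sequence, self.local_mods,
            fixed_carbamidomethyl=fixed_carbamidomethyl,
        )


def cleavage_sites(protein: ProteinRecord) -> list[int]:
    """Positions after which trypsin cuts: K/R, not before P, not terminal."""
    sites = []
    for position in range(protein.first_position, protein.last_position):
        if protein.residue(position) in "KR" and protein.residue(position + 1) != "P":
            sites.append(position)
    return sites


def _normalize_mod_state(
    protein: ProteinRecord,
    mod_state: Iterable[tuple[int, ModificationDef]] | Mapping[int, ModificationDef],
) -> dict[int, ModificationDef]:
    if isinstance(mod_state, Mapping):
        items = mod_state.items()
    else:
        items = list(mod_state)
    state: dict[int, ModificationDef] = {}
    for position, mod in items:
        residue = protein.residue(position)
        if residue not in mod.targets:
            raise InvalidModificationError(
                f"modification {mod.name!r} cannot sit on residue {residue!r} "
                f"at position {position} of protein {protein.id!r}"
            )
        state[position] = mod
    return state


def digest(
    protein: ProteinRecord,
    mod_state: Iterable[tuple[int, ModificationDef]] | Mapping[int, ModificationDef] = (),
    max_missed: int = 0,
) -> list[PeptideForm]:
    """Tryptic peptides of ``protein`` given a fixed modification state.

    Sites carrying a cleavage-blocking modification are removed from the
    candidate cut list entirely: peptides spanning them carry the
    modification and do not count the site as a missed cleavage.  Up to
    ``max_missed`` additional (unblocked) sites may be left uncut.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    state = _normalize_mod_state(protein, mod_state)
    blocked = {p for p, m in state.items() if m.blocks_cleavage}
    eligible = [p for p in cleavage_sites(protein) if p not in blocked]
    boundaries = [protein.first_position - 1] + eligible + [protein.last_position]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            missed = j - i - 1
            if missed > max_missed:
                break
            start, end = boundaries[i] + 1, boundaries[j]
            mods = tuple(
                (p, m) for p, m in sorted(state.items()) if start <= p <= end
            )
            peptides.append(
                PeptideForm(
                    protein_id=protein.id,
                    start=start,
                    end=end,
                    sequence=protein.slice(start, end),
                    mods=mods,
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


class CombinatorialCapError(ValueError):
    """Raised when the modification search space exceeds the configured cap."""


def enumerate_modforms(
    protein: ProteinRecord,
    variable_mods: Sequence[ModificationDef] = (BIOTIN_LC,),
    max_missed: int = 2,
    max_var_mods_per_peptide: int = 2,
    cap: int = 200_000,
) -> list[PeptideForm]:
    """All candidate peptide forms under variable-modification hypotheses.

    This is the theoretical search space for peptide-mass matching: every
    tryptic peptide of the protein under every placement of the variable
    modifications, deduplicated by (span, modification multiset).  An
    internal K at a cleavage site is either carrying a blocking modification
    (a protected site) or counted as a missed cleavage; the C-terminal
    residue of a peptide is never modified.
    """
    if max_missed < 0 or max_var_mods_per_peptide < 0:
        raise ValueError("parameters must be >= 0")
    blocking = [m for m in variable_mods if m.blocks_cleavage]
    nonblocking = [m for m in variable_mods if not m.blocks_cleavage]
    sites = cleavage_sites(protein)
    boundaries = [protein.first_position - 1] + sites + [protein.last_position]
    site_set = set(sites)

    seen: dict[tuple, PeptideForm] = {}

    def emit(form: PeptideForm) -> None:
        if len(seen) >= cap:
            raise CombinatorialCapError(
                f"candidate peptide forms exceed cap of {cap}; lower "
                f"max_var_mods_per_peptide (now {max_var_mods_per_peptide}) "
                f"or max_missed (now {max_missed})"
            )
        seen.setdefault(form.key(), form)

    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            start, end = boundaries[i] + 1, boundaries[j]
            internal = [p for p in sites if start <= p < end]
            if len(internal) > max_missed + max_var_mods_per_peptide:
                break
            sequence = protein.slice(start, end)
            # Internal cut-site residues may be protected by a blocking mod;
            # everything left uncut must fit the missed-cleavage budget.
            blockable = [
                (p, mod)
                for p in internal
                for mod in blocking
                if protein.residue(p) in mod.targets
            ]
            # Free placements: target residues not acting as cut sites
            # (e.g. a K before P), never the C-terminal residue for a
            # blocking mod.
            free: list[tuple[int, ModificationDef]] = []
            for mod in blocking:
                for p in range(start, end):
                    if protein.residue(p) in mod.targets and p not in site_set:
                        free.append((p, mod))
            for mod in nonblocking:
                for p in range(start, end + 1):
                    if protein.residue(p) in mod.targets:
                        free.append((p, mod))
            for n_blocked in range(
                0, min(len(blockable), max_var_mods_per_peptide) + 1
            ):
                for blocked_combo in itertools.combinations(blockable, n_blocked):
                    blocked_positions = {p for p, _ in blocked_combo}
                    if len(blocked_positions) != n_blocked:
                        continue
                    if len(internal) - n_blocked > max_missed:
                        continue
                    budget = max_var_mods_per_peptide - n_blocked
                    for n_free in range(0, min(len(free), budget) + 1):
                        for free_combo in itertools.combinations(free, n_free):
                            positions = [p for p, _ in blocked_combo] + [
                                p for p, _ in free_combo
                            ]
                            if len(set(positions)) != len(positions):
                                continue
                            emit(
                                PeptideForm(
                                    protein_id=protein.id,
                                    start=start,
                                    end=end,
                                    sequence=sequence,
                                    mods=tuple(blocked_combo)
                                    + tuple(free_combo),
                                    missed_cleavages=len(internal) - n_blocked,
                                )
                            )
    forms = sorted(seen.values(), key=lambda p: (p.start, p.end, p.mod_names))
    return forms
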