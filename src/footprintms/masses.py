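"""Monoisotopic mass arithmetic for residues, modifications and charged species.

Covalent-labeling footprinting lives and dies by mass bookkeeping: the
biotinamidocaproyl adduct left on a lysine ε-amine by sulfo-NHS-LC-biotin
adds one well-defined monoisotopic increment (+339.1617 Da), and every
downstream step — digestion, peptide-mass fingerprinting, fragment-ion
ladders — is a sum of such increments.  All masses here are monoisotopic
(most-abundant-isotope) and in daltons; atomic and residue values come from
the IUPAC tables shipped with :mod:`pyteomics.mass`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

#: Mass of a proton (charge carrier in positive-mode MS), Da.
PROTON_MASS = 1.007276

#: Monoisotopic mass of water (released/gained at every peptide bond), Da.
WATER_MASS = _pmass.calculate_mass(formula="H2O")

#: Element symbols accepted in compositions.
ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P"})

#: The 20 canonical residue letters; ambiguity/rare codes are rejected.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses (Da), restricted to the canonical alphabet.
RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a composition names an element outside the allowed set."""


class InvalidResidueError(ValueError):
    """Raised for residues outside the 20-letter canonical alphabet."""


class InvalidModificationError(ValueError):
    """Raised when a modification is placed on a disallowed residue."""


@dataclass(frozen=True)
class ElementalComposition:
    """An elemental formula as element -> count, e.g. the biotin-LC adduct.

    Counts must be non-negative integers over C, H, N, O, S, P.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, count in dict(self.counts).items():
            if element not in ALLOWED_ELEMENTS:
                raise UnknownElementError(
                    f"unknown element symbol {element!r}; allowed: "
                    f"{sorted(ALLOWED_ELEMENTS)}"
                )
            if int(count) != count or count < 0:
                raise ValueError(f"count for {element} must be a non-negative integer")
            if count:
                clean[element] = int(count)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula string such as ``"C16H25N3O3S"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass of a composition, Da.

    Sum of count(e) x monoisotopic atomic mass(e).  The biotinamidocaproyl
    adduct C16H25N3O3S evaluates to 339.1617 Da.
    """
    return sum(
        count * _pmass.nist_mass[element][0][0]
        for element, count in composition.counts.items()
    )


@dataclass(frozen=True)
class ModificationDef:
    """A covalent modification: targets, monoisotopic delta, cleavage effect.

    ``blocks_cleavage`` captures the footprinting-specific rule that a
    biotinylated lysine is no longer a trypsin substrate, so the site is
    protected from digestion.
    """

    name: str
    targets: frozenset[str]
    delta_mono: float
    blocks_cleavage: bool = False
    mode: str = "variable"  # fixed | variable

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("modification must target at least one residue")
        if not all(abs(self.delta_mono) < 1e6 for _ in [0]):
            raise ValueError("delta_mono must be finite")
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be fixed or variable, got {self.mode!r}")
        object.__setattr__(self, "targets", frozenset(self.targets))

    @classmethod
    def from_composition(
        cls,
        name: str,
        targets: Iterable[str],
        composition: ElementalComposition,
        blocks_cleavage: bool = False,
        mode: str = "variable",
    ) -> "ModificationDef":
        return cls(name, frozenset(targets), monoisotopic_mass(composition),
                   blocks_cleavage, mode)


#: Biotinamidocaproyl adduct from sulfo-NHS-LC-biotin on lysine ε-amines.
#: Blocks tryptic cleavage at the labeled lysine.
BIOTIN_LC = ModificationDef.from_composition(
    "biotin-LC", {"K"}, ElementalComposition.from_formula("C16H25N3O3S"),
    blocks_cleavage=True, mode="variable",
)

#: Carbamidomethylation of cysteine from iodoacetamide alkylation.
CARBAMIDOMETHYL = ModificationDef.from_composition(
    "carbamidomethyl", {"C"}, ElementalComposition.from_formula("C2H3NO"),
    blocks_cleavage=False, mode="fixed",
)

#: Default modification registry, keyed by name.
DEFAULT_MODIFICATIONS: Mapping[str, ModificationDef] = {
    BIOTIN_LC.name: BIOTIN_LC,
    CARBAMIDOMETHYL.name: CARBAMIDOMETHYL,
}


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` if every letter is a canonical residue.

    B/Z/X/U and other ambiguity codes are rejected outright: a silently
    wrong mass is worse than a hard failure.
    """
    for i, aa in enumerate(sequence):
        if aa not in CANONICAL_RESIDUES:
            raise InvalidResidueError(
                f"residue {aa!r} at position {i + 1} is not one of the 20 "
                "canonical amino acids"
            )
    return sequence


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, ModificationDef]] = (),
    fixed_carbamidomethyl: bool = False,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide, Da.

    ``mods`` is a list of ``(position, ModificationDef)`` with 1-based
    positions within the peptide; each position must carry a residue the
    modification targets.  With ``fixed_carbamidomethyl`` every cysteine
    additionally gains +57.02146 Da (iodoacetamide alkylation), matching
    standard in-gel digestion workups.
    """
    validate_sequence(sequence)
    total = WATER_MASS + sum(RESIDUE_MASSES[aa] for aa in sequence)
    for position, mod in mods:
        if not 1 <= position <= len(sequence):
            raise InvalidModificationError(
                f"modification position {position} outside peptide of length "
                f"{len(sequence)}"
            )
        residue = sequence[position - 1]
        if residue not in mod.targets:
            raise InvalidModificationError(
                f"modification {mod.name!r} cannot sit on residue {residue!r} "
                f"at position {position}"
            )
        total += mod.delta_mono
    if fixed_carbamidomethyl:
        total += sequence.count("C") * CARBAMIDOMETHYL.delta_mono
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of the protonated species ``[M + zH]^z+``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def protein_label_shift(n_sites: int, mod: ModificationDef = BIOTIN_LC) -> float:
    """Total mass shift (Da) if ``n_sites`` residues each carry one adduct.

    For ATR's 175 lysines under saturating biotinylation this is 59.35 kDa.
    """
    if n_sites < 0:
        raise ValueError(f"n_sites must be >= 0, got {n_sites}")
    return n_sites * mod.delta_mono
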