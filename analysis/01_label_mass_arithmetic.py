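#!/usr/bin/env python
"""Mass arithmetic of NHS-biotin lysine labeling.

Computes the monoisotopic mass of the biotinamidocaproyl adduct that
sulfo-NHS-LC-biotin leaves on a lysine epsilon-amine, and the total mass
shift of a 175-lysine protein under saturating labeling.  Writes
results/label_mass.json.
"""

import json
from pathlib import Path

from footprintms.masses import (
    BIOTIN_LC,
    ElementalComposition,
    monoisotopic_mass,
    protein_label_shift,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    adduct = ElementalComposition.from_formula("C16H25N3O3S")
    mass = monoisotopic_mass(adduct)
    shift = protein_label_shift(175, BIOTIN_LC)
    print(f"biotinamidocaproyl adduct (C16H25N3O3S): {mass:.4f} Da per lysine")
    print(f"saturating labeling of 175 lysines: {shift / 1000:.2f} kDa")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "label_mass.json"
    out.write_text(
        json.dumps(
            {
                "adduct_mass_da": round(mass, 4),
                "saturation_sites": 175,
                "saturation_shift_kda": round(shift / 1000, 2),
            },
            indent=2,
        )
        + "\n"
    )
    print(f"-> {out}")


if __name__ == "__main__":
    main()
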