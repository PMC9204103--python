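from pathlib import Path

import pytest

from footprintms.digest import ProteinRecord
from footprintms.io_formats import read_printed_peptides

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

# Independent residue-mass table for oracle computations: monoisotopic
# values transcribed from standard references, NOT taken from the package.
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565
ORACLE_PROTON = 1.007276


def oracle_peptide_mass(sequence: str, n_biotin: int = 0) -> float:
    """Hand-rolled residue-mass summation, independent of the package."""
    return (
        sum(ORACLE_RESIDUE_MASS[aa] for aa in sequence)
        + ORACLE_WATER
        + n_biotin * 339.16166
    )


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def dimer_peptides(data_dir):
    return read_printed_peptides(data_dir / "dimer_interface_peptides.tsv")


@pytest.fixture
def protection_region() -> ProteinRecord:
    # the kinase-proximal region whose internal lysine (K1994) is protected
    # from digestion when biotinylated
    return ProteinRecord("region", "GVELCFPENETPPEGKNMLIHGR", numbering_offset=1979)
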