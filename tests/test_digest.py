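import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footprintms.digest import (
    CombinatorialCapError,
    PeptideForm,
    ProteinRecord,
    cleavage_sites,
    digest,
    enumerate_modforms,
)
from footprintms.masses import (
    BIOTIN_LC,
    WATER_MASS,
    InvalidModificationError,
    peptide_mass,
)

sequences = st.text(alphabet="AGKRPLSEK", min_size=1, max_size=30)


def brute_modforms(seq: str, max_missed: int, max_var: int) -> set:
    """Independent enumeration oracle: scan every substring and label
    assignment directly against the digestion rules."""
    n = len(seq)

    def is_site(p):  # 1-based, cut after p
        return p < n and seq[p - 1] in "KR" and seq[p] != "P"

    sites = {p for p in range(1, n + 1) if is_site(p)}
    out = set()
    for s in range(1, n + 1):
        if not (s == 1 or is_site(s - 1)):
            continue
        for e in range(s, n + 1):
            if not (e == n or is_site(e)):
                continue
            internal = sorted(p for p in sites if s <= p < e)
            k_sites = [p for p in internal if seq[p - 1] == "K"]
            free_k = [
                p for p in range(s, e) if seq[p - 1] == "K" and p not in sites
            ]
            for n_blocked in range(len(k_sites) + 1):
                for blocked in itertools.combinations(k_sites, n_blocked):
                    missed = len(internal) - n_blocked
                    if missed > max_missed:
                        continue
                    for n_extra in range(len(free_k) + 1):
                        for extra in itertools.combinations(free_k, n_extra):
                            mods = frozenset(blocked) | frozenset(extra)
                            if len(mods) > max_var:
                                continue
                            out.add((s, e, mods, missed))
    return out


def forms_as_tuples(forms) -> set:
    return {
        (
            f.start,
            f.end,
            frozenset(p for p, m in f.mods if m.name == "biotin-LC"),
            f.missed_cleavages,
        )
        for f in forms
    }


class TestCleavageSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AKPR", []),  # K-P suppressed, terminal R not a site
            ("AAAA", []),
            ("AKGR", [2]),
            ("GVELCFPENETPPEGKNMLIHGR", [16]),
        ],
    )
    def test_examples(self, seq, expected):
        assert cleavage_sites(ProteinRecord("p", seq)) == expected

    def test_numbering_offset_respected(self, protection_region):
        assert cleavage_sites(protection_region) == [1994]


class TestDigest:
    def test_unmodified_region_gives_two_peptides(self, protection_region):
        peptides = digest(protection_region)
        assert [p.sequence for p in peptides] == ["GVELCFPENETPPEGK", "NMLIHGR"]

    def test_modified_lysine_protects_cleavage(self, protection_region):
        peptides = digest(protection_region, {1994: BIOTIN_LC})
        assert len(peptides) == 1
        (peptide,) = peptides
        assert peptide.sequence == "GVELCFPENETPPEGKNMLIHGR"
        assert peptide.mod_names == ((1994, "biotin-LC"),)
        # a protected site is not a missed cleavage
        assert peptide.missed_cleavages == 0

    def test_internal_modified_k_retained_cterm_k_free(self):
        # BH3-region peptide: internal K459 labeled, C-terminal K467 cut site
        protein = ProteinRecord("bh3", "VDMNQKSILWSALK", numbering_offset=454)
        peptides = digest(protein, {459: BIOTIN_LC})
        assert len(peptides) == 1
        assert peptides[0].sequence == "VDMNQKSILWSALK"
        assert peptides[0].mod_names == ((459, "biotin-LC"),)

    def test_mod_on_non_target_rejected(self):
        with pytest.raises(InvalidModificationError):
            digest(ProteinRecord("p", "AGR"), {2: BIOTIN_LC})

    @given(seq=sequences)
    @settings(max_examples=60, deadline=None)
    def test_partition_invariant(self, seq):
        protein = ProteinRecord("p", seq)
        peptides = digest(protein)
        assert "".join(p.sequence for p in peptides) == seq
        starts = [p.start for p in peptides]
        assert starts == sorted(starts)

    @given(seq=sequences)
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation(self, seq):
        protein = ProteinRecord("p", seq)
        peptides = digest(protein)
        total = sum(peptide_mass(p.sequence) for p in peptides)
        expected = peptide_mass(seq) + (len(peptides) - 1) * WATER_MASS
        assert total == pytest.approx(expected, abs=1e-6)

    @given(seq=sequences, m=st.integers(min_value=0, max_value=2))
    @settings(max_examples=40, deadline=None)
    def test_missed_cleavage_monotonicity(self, seq, m):
        protein = ProteinRecord("p", seq)
        smaller = {p.key() for p in digest(protein, max_missed=m)}
        larger = {p.key() for p in digest(protein, max_missed=m + 1)}
        assert smaller <= larger


class TestEnumerateModforms:
    def test_small_example_matches_oracle(self):
        protein = ProteinRecord("p", "AKGKR")
        forms = enumerate_modforms(
            protein, max_missed=1, max_var_mods_per_peptide=2
        )
        assert forms_as_tuples(forms) == brute_modforms("AKGKR", 1, 2)
        sequences_seen = {f.sequence for f in forms}
        assert {"AK", "GK", "AKGK", "AKGKR"} <= sequences_seen

    def test_no_variable_mods_reduces_to_digest(self):
        protein = ProteinRecord("p", "AKGLRPKSEK")
        plain = {p.key() for p in digest(protein, max_missed=2)}
        enumerated = {
            p.key()
            for p in enumerate_modforms(
                protein, variable_mods=(), max_missed=2
            )
        }
        assert plain == enumerated

    def test_lysine_free_protein_ignores_biotin(self):
        protein = ProteinRecord("p", "AGLRSEGR")
        with_mod = enumerate_modforms(protein, max_missed=1)
        without = enumerate_modforms(protein, variable_mods=(), max_missed=1)
        assert forms_as_tuples(with_mod) == forms_as_tuples(without)

    def test_cap_exceeded_raises(self):
        protein = ProteinRecord("p", "KAKAKAKAKAKAKAKAKAKA")
        with pytest.raises(CombinatorialCapError, match="max_var_mods"):
            enumerate_modforms(
                protein, max_missed=2, max_var_mods_per_peptide=8, cap=10
            )

    @given(
        seq=sequences,
        max_missed=st.integers(min_value=0, max_value=2),
        max_var=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random_sequences(self, seq, max_missed, max_var):
        protein = ProteinRecord("p", seq)
        forms = enumerate_modforms(
            protein, max_missed=max_missed, max_var_mods_per_peptide=max_var
        )
        assert forms_as_tuples(forms) == brute_modforms(seq, max_missed, max_var)

    def test_cterminal_lysine_never_modified(self):
        protein = ProteinRecord("p", "AGKPLK")  # protein ends in K
        forms = enumerate_modforms(protein, max_missed=2,
                                   max_var_mods_per_peptide=3)
        for form in forms:
            assert all(pos != form.end for pos, _ in form.mods)


class TestPeptideForm:
    def test_blocking_mod_on_cterm_rejected(self):
        with pytest.raises(InvalidModificationError, match="C-terminal"):
            PeptideForm("p", 1, 2, "AK", mods=((2, BIOTIN_LC),))

    def test_sequence_span_consistency(self):
        with pytest.raises(ValueError):
            PeptideForm("p", 1, 3, "AK")
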