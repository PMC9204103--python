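import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ORACLE_PROTON, ORACLE_RESIDUE_MASS, ORACLE_WATER

from footprintms.digest import PeptideForm
from footprintms.io_formats import PeakList
from footprintms.masses import BIOTIN_LC, PROTON_MASS
from footprintms.site_localization import (
    _hypothesis_form,
    ascore,
    fragment_ions,
    site_determining_ions,
)

peptides = st.text(alphabet="ACDEFGHILMNQSTVWY", min_size=2, max_size=20)


def ladder_spectrum(form, drop=(), base=100.0):
    ions = [i for i in fragment_ions(form) if (i.series, i.index) not in drop]
    return PeakList(
        peaks=tuple(sorted((i.mz, base - i.index) for i in ions)),
        level="MS2",
    )


class TestFragmentIons:
    def test_y1_of_arginine_terminated_peptide(self):
        form = PeptideForm("p", 1, 7, "NMLIHGR")
        y1 = next(
            i for i in fragment_ions(form) if i.series == "y" and i.index == 1
        )
        assert y1.mz == pytest.approx(
            ORACLE_RESIDUE_MASS["R"] + ORACLE_WATER + ORACLE_PROTON, abs=1e-4
        )
        assert y1.mz == pytest.approx(175.1190, abs=1e-3)

    def test_biotin_shifts_b2_by_adduct_mass(self):
        seq = "QKAESLQISLEYSGLK"
        base = PeptideForm("p", 468, 483, seq)
        modded = PeptideForm("p", 468, 483, seq, mods=((469, BIOTIN_LC),))

        def b2(form):
            return next(
                i for i in fragment_ions(form)
                if i.series == "b" and i.index == 2
            ).mz

        assert b2(modded) - b2(base) == pytest.approx(339.1617, abs=1e-3)

    @given(seq=peptides)
    @settings(max_examples=50, deadline=None)
    def test_complementarity(self, seq):
        form = PeptideForm("p", 1, len(seq), seq)
        ions = {(i.series, i.index): i.mz for i in fragment_ions(form)}
        total = form.mass() + 2 * PROTON_MASS
        for i in range(1, len(seq)):
            assert ions[("b", i)] + ions[("y", len(seq) - i)] == pytest.approx(
                total, abs=1e-9
            )

    def test_rejections(self):
        form = PeptideForm("p", 1, 3, "AGK")
        with pytest.raises(ValueError):
            fragment_ions(form, series=())
        with pytest.raises(ValueError):
            fragment_ions(form, series={"c"})


class TestSiteDeterminingIons:
    def test_enumeration_matches_direct_oracle(self):
        # sites at local positions 2 and 6 of a 14-mer
        form = PeptideForm("p", 1, 14, "AKGGGKGGGGGGGR")
        sd = site_determining_ions(form, 2, 6)
        expected = {("b", i) for i in range(2, 6)} | {
            ("y", j) for j in range(9, 13)
        }
        for site in (2, 6):
            assert {(i.series, i.index) for i in sd[site]} == expected

    def test_adjacent_sites_minimal_set(self):
        form = PeptideForm("p", 1, 6, "AKKGGR")
        sd = site_determining_ions(form, 2, 3)
        assert {(i.series, i.index) for i in sd[2]} == {("b", 2), ("y", 4)}

    def test_extreme_sites_maximal_set(self):
        form = PeptideForm("p", 1, 6, "KGGGKR")
        sd = site_determining_ions(form, 1, 5)
        assert {(i.series, i.index) for i in sd[1]} == {
            ("b", i) for i in range(1, 5)
        } | {("y", j) for j in range(2, 6)}

    def test_identical_sites_rejected(self):
        form = PeptideForm("p", 1, 6, "AKKGGR")
        with pytest.raises(ValueError):
            site_determining_ions(form, 2, 2)


class TestAscore:
    @pytest.fixture
    def two_site_form(self):
        return PeptideForm(
            "p", 1, 10, "AKGGGGKGGR", mods=((2, BIOTIN_LC),)
        )

    def test_clean_ladder_localizes_with_high_confidence(self, two_site_form):
        spectrum = ladder_spectrum(_hypothesis_form(two_site_form, 2, BIOTIN_LC))
        result = ascore(spectrum, two_site_form, [2, 7])
        assert result.best_site == 2
        assert result.delta_ascore > 19

    def test_symmetric_evidence_is_ambiguous(self, two_site_form):
        lad_a = fragment_ions(_hypothesis_form(two_site_form, 2, BIOTIN_LC))
        lad_b = fragment_ions(_hypothesis_form(two_site_form, 7, BIOTIN_LC))
        mzs = sorted({round(i.mz, 6) for i in lad_a + lad_b})
        spectrum = PeakList(
            peaks=tuple((mz, 50.0) for mz in mzs), level="MS2"
        )
        result = ascore(spectrum, two_site_form, [2, 7])
        assert result.delta_ascore == 0.0

    def test_candidate_order_irrelevant(self, two_site_form):
        spectrum = ladder_spectrum(_hypothesis_form(two_site_form, 7, BIOTIN_LC))
        forward = ascore(spectrum, two_site_form, [2, 7])
        backward = ascore(spectrum, two_site_form, [7, 2])
        assert forward.best_site == backward.best_site == 7
        assert forward.delta_ascore == backward.delta_ascore

    def test_single_candidate_unambiguous_sentinel(self, two_site_form):
        result = ascore(PeakList(peaks=()), two_site_form, [2])
        assert result.unambiguous and result.best_site == 2
        assert math.isinf(result.delta_ascore)

    def test_empty_spectrum_zero_scores(self, two_site_form):
        result = ascore(PeakList(peaks=()), two_site_form, [2, 7])
        assert result.delta_ascore == 0.0
        assert not result.is_confident()

    def test_internal_lysine_chosen_in_bh3_peptide(self):
        # K459 internal in 454..467; C-terminal K467 is a cleaved site and
        # excluded a priori, so localization is between internal lysines
        form = PeptideForm(
            "p", 454, 467, "VDMNQKSILWSALK", mods=((459, BIOTIN_LC),)
        )
        spectrum = ladder_spectrum(form)
        result = ascore(spectrum, form, [459])
        assert result.best_site == 459 and result.unambiguous

    def test_irrelevant_peaks_do_not_inflate_confidence(self, two_site_form):
        truth = _hypothesis_form(two_site_form, 2, BIOTIN_LC)
        spectrum = ladder_spectrum(truth)
        base = ascore(spectrum, two_site_form, [2, 7], depths=(10,))
        extra = tuple(
            sorted(spectrum.peaks + tuple((151.0 + 13 * i, 5.0) for i in range(8)))
        )
        noisy = ascore(
            PeakList(peaks=extra, level="MS2"),
            two_site_form, [2, 7], depths=(10,),
        )
        assert noisy.delta_ascore <= base.delta_ascore + 1e-9

    def test_scores_nonnegative(self, two_site_form):
        spectrum = ladder_spectrum(_hypothesis_form(two_site_form, 2, BIOTIN_LC),
                                   drop={("b", 2), ("y", 8)})
        result = ascore(spectrum, two_site_form, [2, 7])
        assert result.delta_ascore >= 0.0
        assert all(v >= 0.0 for v in result.site_scores.values())
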