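import math

import pandas as pd
import pytest

from footprintms.digest import PeptideForm
from footprintms.footprint_compare import (
    DEFAULT_DOMAINS,
    AccessibilityMap,
    DifferentialReport,
    DomainTable,
    annotate_domains,
    build_accessibility_map,
    compare_states,
    count_modified_in_printed_list,
    domain_tally,
    pool_maps,
)
from footprintms.io_formats import PrintedPeptide
from footprintms.site_localization import SiteLocalizationResult


def loc(site, delta, sites=None, seq="AKGGGGKGGR", start=1):
    form = PeptideForm("atr", start, start + len(seq) - 1, seq)
    sites = tuple(sites or (site,))
    return SiteLocalizationResult(
        peptide=form,
        candidate_sites=sites,
        site_scores={s: delta for s in sites},
        best_site=site,
        delta_ascore=delta,
        unambiguous=len(sites) == 1,
    )


class TestBuildAccessibilityMap:
    def test_confident_single_localization_called(self):
        result = build_accessibility_map("trans", [], [loc(1994, math.inf)])
        assert result.positions == {1994}

    def test_below_threshold_filtered(self):
        below = loc(7, 5.0, sites=(2, 7))
        assert build_accessibility_map("s", [], [below]).positions == set()

    def test_anti_monotone_in_threshold(self):
        locs = [loc(2, 25.0, sites=(2, 7)), loc(7, 12.0, sites=(2, 7))]
        lenient = build_accessibility_map("s", [], locs, min_delta_ascore=10)
        strict = build_accessibility_map("s", [], locs, min_delta_ascore=20)
        assert strict.positions <= lenient.positions
        assert lenient.positions == {2, 7} and strict.positions == {2}

    def test_min_witnesses(self):
        locs = [loc(2, 30.0, sites=(2, 7))]
        assert build_accessibility_map(
            "s", [], locs, min_witnesses=2
        ).positions == set()
        assert build_accessibility_map(
            "s", [], locs * 2, min_witnesses=2
        ).positions == {2}


class TestCompareStates:
    @pytest.fixture
    def published_maps(self, data_dir):
        calls = pd.read_csv(data_dir / "modified_lysines_by_state.tsv", sep="\t")
        return {
            state: AccessibilityMap.from_positions(
                state, "atr", group["residue"].tolist()
            )
            for state, group in calls.groupby("state")
        }

    def test_published_differential_counts(self, published_maps):
        report = compare_states(published_maps["cis"], published_maps["trans"])
        assert report.unique_to_a == {459, 469}
        assert report.unique_to_b == {818, 1005, 1057, 1703, 1994, 2200, 2413}
        assert report.shared == {2859}

    def test_domain_annotation_of_published_sites(self, published_maps):
        report = annotate_domains(
            compare_states(published_maps["cis"], published_maps["trans"]),
            DEFAULT_DOMAINS,
        )
        assert report.domain_labels[469] == "BH3"
        assert report.domain_labels[459] == "flank:BH3"
        assert report.domain_labels[2413] == "KD"
        assert report.domain_labels[818] == "unassigned"
        tally = domain_tally(report)
        assert tally["BH3"] == {"unique_to_cis": 1}
        assert tally["KD"]["unique_to_trans"] == 1

    def test_mirror_symmetry(self, published_maps):
        fwd = compare_states(published_maps["cis"], published_maps["trans"])
        rev = compare_states(published_maps["trans"], published_maps["cis"])
        assert fwd.unique_to_a == rev.unique_to_b
        assert fwd.unique_to_b == rev.unique_to_a
        assert fwd.shared == rev.shared

    def test_identity_and_disjoint_cases(self):
        a = AccessibilityMap.from_positions("a", "p", [1, 5])
        same = compare_states(a, AccessibilityMap.from_positions("b", "p", [1, 5]))
        assert same.unique_to_a == same.unique_to_b == frozenset()
        disjoint = compare_states(
            a, AccessibilityMap.from_positions("b", "p", [9])
        )
        assert disjoint.shared == frozenset()
        assert disjoint.unique_to_a == {1, 5} and disjoint.unique_to_b == {9}

    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            DifferentialReport(
                "a", "b",
                unique_to_a=frozenset({1}), unique_to_b=frozenset({1}),
                shared=frozenset(),
            )

    def test_pooling_rules(self):
        wt = AccessibilityMap.from_positions("WT", "p", [459, 100])
        s428a = AccessibilityMap.from_positions("S428A", "p", [469, 100])
        union = pool_maps("cis", [wt, s428a])
        assert union.positions == {100, 459, 469}
        inter = pool_maps("cis", [wt, s428a], rule="intersection")
        assert inter.positions == {100}


class TestDomainTable:
    def test_flank_window_boundaries(self):
        table = DomainTable(entries=(("BH3", 461, 474),), flank_window=5)
        assert table.classify(460) == "flank:BH3"
        assert table.classify(456) == "flank:BH3"
        assert table.classify(455) == "unassigned"
        assert table.classify(479) == "flank:BH3"

    def test_invalid_entry(self):
        with pytest.raises(ValueError):
            DomainTable(entries=(("X", 10, 5),))


class TestPrintedListCounting:
    def test_dimer_interface_counts(self, dimer_peptides):
        trans = [p for p in dimer_peptides if p.isoform == "trans"]
        cis = [p for p in dimer_peptides if p.isoform == "cis"]
        assert count_modified_in_printed_list(trans) == (13, 2)
        assert count_modified_in_printed_list(cis) == (14, 1)

    def test_all_uppercase_gives_zero(self):
        peptides = [PrintedPeptide("x", "AKWLWSK"), PrintedPeptide("x", "AMLLVGR")]
        assert count_modified_in_printed_list(peptides) == (2, 0)

    def test_lowercase_c_tolerated_other_marks_rejected(self):
        ok = [PrintedPeptide("x", "GVELcFPENETPPEGK")]
        assert count_modified_in_printed_list(ok) == (1, 0)
        with pytest.raises(ValueError, match="unknown lowercase"):
            count_modified_in_printed_list([PrintedPeptide("x", "AGmK")])
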