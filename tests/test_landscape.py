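import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cliffscape import (
    LandscapeThresholds,
    RegionLabel,
    build_sas_map,
    classify_pair,
    cliff_generator_frequencies,
    consensus_counts,
    consensus_generator_ranking,
    sali,
    summarize_regions,
)

from conftest import random_table

TH = LandscapeThresholds(t_sim={"S": 0.4712}, t_act=1.0)

# region counts per fingerprint as printed for the published 50-compound
# G9a/DNMT1 set; used here purely as consensus-arithmetic inputs
G9A_COUNTS = {
    "MACCS": {"AC": 268, "SM": 320, "SC": 290, "ND": 347},
    "PUBCHEM": {"AC": 432, "SM": 468, "SC": 142, "ND": 183},
    "ECFP4": {"AC": 324, "SM": 439, "SC": 171, "ND": 291},
}
DNMT1_COUNTS = {
    "MACCS": {"AC": 55, "SM": 532, "SC": 488, "ND": 147},
    "PUBCHEM": {"AC": 92, "SM": 755, "SC": 262, "ND": 110},
    "ECFP4": {"AC": 177, "SM": 949, "SC": 71, "ND": 25},
}


class TestSali:
    def test_zero_numerator(self):
        assert sali(6.0, 6.0, 0.7) == 0.0

    def test_hand_substitution(self):
        # |8.69 - 5.0| / (1 - 0.8) = 3.69 / 0.2
        assert sali(8.69, 5.0, 0.8) == pytest.approx(18.45)

    def test_identical_structures_divergent(self):
        assert sali(7.0, 5.0, 1.0) == math.inf
        assert sali(7.0, 7.0, 1.0) == 0.0

    def test_similarity_domain(self):
        with pytest.raises(ValueError):
            sali(7.0, 5.0, 1.2)

    @settings(deadline=None, max_examples=1000)
    @given(
        a=st.floats(0, 14), b=st.floats(0, 14),
        sim=st.floats(0, 1, exclude_max=True),
    )
    def test_closed_form_oracle(self, a, b, sim):
        """sali() equals direct substitution into |Ai−Aj|/(1−sim)."""
        assert sali(a, b, sim) == pytest.approx(abs(a - b) / (1.0 - sim))

    @given(
        dact=st.floats(0.1, 5), sims=st.tuples(st.floats(0, 0.99), st.floats(0, 0.99))
    )
    def test_increasing_in_similarity(self, dact, sims):
        lo, hi = sorted(sims)
        assert sali(dact, 0.0, lo) <= sali(dact, 0.0, hi)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "sim,dact,expected",
        [
            (0.9, 2.5, RegionLabel.ACTIVITY_CLIFF),
            (0.9, 0.5, RegionLabel.SMOOTH_SAR),
            (0.2, 0.5, RegionLabel.SIMILARITY_CLIFF),
            (0.2, 3.0, RegionLabel.NOT_DESCRIPTIVE),
            # boundary values fall on the "low" side of each axis
            (0.4712, 0.5, RegionLabel.SIMILARITY_CLIFF),
            (0.9, 1.0, RegionLabel.SMOOTH_SAR),
            (0.4712, 1.0, RegionLabel.SIMILARITY_CLIFF),
        ],
    )
    def test_regions(self, sim, dact, expected):
        assert classify_pair(sim, dact, TH, "S") is expected

    @settings(deadline=None)
    @given(sim=st.floats(0, 1), dact=st.floats(0, 10))
    def test_total_function(self, sim, dact):
        assert classify_pair(sim, dact, TH, "S") in RegionLabel

    @settings(deadline=None)
    @given(sim=st.floats(0, 1), dact=st.floats(0, 10),
           t1=st.floats(0.1, 3), t2=st.floats(0.1, 3))
    def test_raising_t_act_only_moves_toward_small_dact_regions(self, sim, dact, t1, t2):
        lo, hi = sorted((t1, t2))
        before = classify_pair(sim, dact, LandscapeThresholds({"S": 0.5}, lo), "S")
        after = classify_pair(sim, dact, LandscapeThresholds({"S": 0.5}, hi), "S")
        allowed = {
            RegionLabel.ACTIVITY_CLIFF: {RegionLabel.ACTIVITY_CLIFF, RegionLabel.SMOOTH_SAR},
            RegionLabel.NOT_DESCRIPTIVE: {RegionLabel.NOT_DESCRIPTIVE, RegionLabel.SIMILARITY_CLIFF},
            RegionLabel.SMOOTH_SAR: {RegionLabel.SMOOTH_SAR},
            RegionLabel.SIMILARITY_CLIFF: {RegionLabel.SIMILARITY_CLIFF},
        }
        assert after in allowed[before]


class TestBuildSasMap:
    def test_pair_count_combinatorics(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, 6)
        sas = build_sas_map(table, schemes=["MACCS"])
        assert len(sas.pairs) == 15

    def test_two_compounds_one_pair(self):
        rng = np.random.default_rng(1)
        sas = build_sas_map(random_table(rng, 2), schemes=["MACCS"])
        assert len(sas.pairs) == 1

    def test_auto_thresholds_are_per_scheme_means(self):
        rng = np.random.default_rng(2)
        sas = build_sas_map(random_table(rng, 8), schemes=["MACCS", "ECFP4"])
        for scheme in sas.schemes:
            assert sas.thresholds.t_sim[scheme] == pytest.approx(
                sas.mean_similarity[scheme]
            )
        assert sas.thresholds.t_act == 1.0

    def test_labels_match_bruteforce_classify(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, 6)
        sas = build_sas_map(table, schemes=["MACCS", "ECFP4"])
        for pair, (i, j) in zip(
            sas.pairs, itertools.combinations(range(len(table)), 2)
        ):
            for scheme in sas.schemes:
                for target in sas.targets:
                    expected = classify_pair(
                        pair.similarity[scheme],
                        pair.activity_difference[target],
                        sas.thresholds,
                        scheme,
                    )
                    assert pair.region[(scheme, target)] is expected


class TestSummarizeRegions:
    @pytest.mark.parametrize("seed", range(10))
    def test_counts_equal_bruteforce_tally(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, int(rng.integers(3, 11)))
        sas = build_sas_map(table, schemes=["MACCS", "ECFP4"])
        for target in sas.targets:
            summary = summarize_regions(sas, target)
            for scheme in sas.schemes:
                tally = {r: 0 for r in RegionLabel}
                for pair in sas.pairs:
                    tally[pair.region[(scheme, target)]] += 1
                assert summary.counts[scheme] == tally
                assert sum(tally.values()) == table.n_pairs

    def test_equal_activities_yield_no_cliffs(self):
        from cliffscape import ActivityTable, CompoundRecord

        pool = ["c1ccccc1", "CCO", "CCN", "CC(=O)O", "C1CCNCC1", "c1ccncc1"]
        table = ActivityTable(
            compounds=[
                CompoundRecord(str(i), s, {"T": 6.0})
                for i, s in enumerate(pool, 1)
            ],
            targets=["T"],
        )
        sas = build_sas_map(table, schemes=["MACCS"])
        summary = summarize_regions(sas, "T")
        assert summary.counts["MACCS"][RegionLabel.ACTIVITY_CLIFF] == 0
        assert summary.counts["MACCS"][RegionLabel.NOT_DESCRIPTIVE] == 0

    def test_consensus_within_one_of_total(self):
        rng = np.random.default_rng(12)
        sas = build_sas_map(random_table(rng, 9))
        summary = summarize_regions(sas, "T1")
        assert abs(sum(summary.consensus.values()) - summary.total_pairs) <= 1

    def test_summary_dataframe_has_consensus_row(self):
        rng = np.random.default_rng(13)
        sas = build_sas_map(random_table(rng, 5), schemes=["MACCS", "ECFP4"])
        df = summarize_regions(sas, "T1").to_dataframe()
        assert list(df["fingerprint"]) == ["MACCS", "ECFP4", "Consensus"]


class TestConsensusCounts:
    def test_published_g9a_row(self):
        assert consensus_counts(G9A_COUNTS) == {
            "AC": 341, "SM": 409, "SC": 201, "ND": 274
        }

    def test_published_dnmt1_row(self):
        assert consensus_counts(DNMT1_COUNTS) == {
            "AC": 108, "SM": 745, "SC": 274, "ND": 94
        }

    def test_mean_of_equal_counts(self):
        counts = {"A": {"x": 7}, "B": {"x": 7}, "C": {"x": 7}}
        assert consensus_counts(counts) == {"x": 7}

    def test_half_rounds_up(self):
        counts = {"A": {"x": 1}, "B": {"x": 2}}
        assert consensus_counts(counts) == {"x": 2}  # 1.5 → 2, half away from zero

    def test_mismatched_keys(self):
        with pytest.raises(ValueError, match="mismatch"):
            consensus_counts({"A": {"x": 1}, "B": {"y": 1}})

    def test_single_scheme_rejected(self):
        with pytest.raises(ValueError):
            consensus_counts({"A": {"x": 1}})


class TestCliffGenerators:
    def _sas_with_regions(self, regions):
        """Build a minimal SASMap stub carrying prelabeled pairs."""
        from cliffscape.landscape import PairComparison, SASMap

        pairs = []
        for (i, j), region in regions.items():
            p = PairComparison(i=i, j=j, similarity={"S": 0.9},
                              activity_difference={"T": 2.0})
            p.region[("S", "T")] = region
            p.sali[("S", "T")] = 1.0
            pairs.append(p)
        return SASMap(pairs=pairs, thresholds=TH, schemes=["S"], targets=["T"],
                      mean_similarity={"S": 0.5})

    def test_single_cliff_pair_splits_evenly(self):
        sas = self._sas_with_regions({("a", "b"): RegionLabel.ACTIVITY_CLIFF,
                                      ("a", "c"): RegionLabel.SMOOTH_SAR})
        assert cliff_generator_frequencies(sas, "S", "T") == {"a": 0.5, "b": 0.5}

    def test_membership_normalization(self):
        # X in 3 of 5 cliff pairs → 3 / (2*5) = 0.3
        regions = {
            ("X", "a"): RegionLabel.ACTIVITY_CLIFF,
            ("X", "b"): RegionLabel.ACTIVITY_CLIFF,
            ("X", "c"): RegionLabel.ACTIVITY_CLIFF,
            ("d", "e"): RegionLabel.ACTIVITY_CLIFF,
            ("f", "g"): RegionLabel.ACTIVITY_CLIFF,
        }
        freqs = cliff_generator_frequencies(self._sas_with_regions(regions), "S", "T")
        assert freqs["X"] == pytest.approx(0.3)
        assert next(iter(freqs)) == "X"  # descending order
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_no_cliffs_empty_mapping(self):
        sas = self._sas_with_regions({("a", "b"): RegionLabel.SMOOTH_SAR})
        assert cliff_generator_frequencies(sas, "S", "T") == {}

    def test_consensus_ranking_orders_by_mean_rank(self):
        rng = np.random.default_rng(21)
        sas = build_sas_map(random_table(rng, 8), schemes=["MACCS", "ECFP4"])
        df = consensus_generator_ranking(sas, "T1")
        if not df.empty:
            assert list(df["mean_rank"]) == sorted(df["mean_rank"])
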