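import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import bh_oracle
from nichegrn.errors import DegenerateDistributionError, FormatError
from nichegrn.discretize import GeneConditionSummary
from nichegrn.io import (ACTIVATION, INHIBITION, TRANSCRIPTION,
                         BaselineReference, Edge, PriorNetwork)
from nichegrn.pairs import (all_pair_statistics, bh_adjust, filter_candidates,
                            pair_statistic, robust_z_test, evaluate_pairs)


def summary_from(d):
    return GeneConditionSummary(pd.DataFrame(d).T.rename(
        columns={0: "stem", 1: "diff"}))


class TestPairStatistic:
    def test_equal_genes_give_zero(self):
        s = summary_from({"a": [3.0, 5.0], "b": [3.0, 5.0]})
        assert pair_statistic(s, "a", "b", "stem", "diff").d == 0.0

    def test_direct_arithmetic(self):
        s = summary_from({"a": [3.0, 5.0], "b": [3.0, 1.0]})
        assert pair_statistic(s, "a", "b", "stem", "diff").d == 4.0

    def test_missing_gene_named(self):
        s = summary_from({"a": [1.0, 2.0]})
        with pytest.raises(FormatError, match="ghost"):
            pair_statistic(s, "a", "ghost", "stem", "diff")

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=4))
    def test_antisymmetry(self, vals):
        s = summary_from({"a": vals[:2], "b": vals[2:]})
        fwd = pair_statistic(s, "a", "b", "stem", "diff").d
        rev = pair_statistic(s, "b", "a", "stem", "diff").d
        assert fwd + rev == pytest.approx(0.0)


class TestAllPairStatistics:
    @pytest.mark.parametrize("n,expected", [(3, 3), (10, 45)])
    def test_pair_count(self, n, expected):
        genes = {f"g{i:02d}": [float(i), float(i * 2)] for i in range(n)}
        table = all_pair_statistics(summary_from(genes), list(genes),
                                    "stem", "diff")
        assert len(table) == expected
        assert (table["gene1"] < table["gene2"]).all()

    def test_values_match_per_pair_calls(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": list(rng.normal(5, 2, 2)) for i in range(6)}
        s = summary_from(genes)
        table = all_pair_statistics(s, list(genes), "stem", "diff")
        for row in table.itertuples(index=False):
            assert row.d == pytest.approx(
                pair_statistic(s, row.gene1, row.gene2, "stem", "diff").d)

    def test_duplicate_tfs_rejected(self):
        s = summary_from({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(FormatError, match="duplicate"):
            all_pair_statistics(s, ["a", "b", "a"], "stem", "diff")


class TestRobustZ:
    def test_outlier_gets_large_z_without_inflating_scale(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 499), [50.0]])
        z, p = robust_z_test(vals)
        assert abs(z[-1]) > 20 and np.isfinite(z[-1])
        # core z-scores still near standard normal
        assert np.std(z[:-1]) == pytest.approx(1.0, abs=0.15)

    def test_null_calibration_10k_draws(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=10000)
        _, p = robust_z_test(vals)
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(vals))
        assert abs(frac - 0.05) < 3 * se

    def test_constant_values_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            robust_z_test(np.zeros(50))

    def test_minimum_size_enforced(self):
        with pytest.raises(FormatError, match="20"):
            robust_z_test(np.arange(10.0))

    def test_without_consistency_correction_scale_shrinks(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=5000)
        z_corr, _ = robust_z_test(vals)
        z_raw, _ = robust_z_test(vals, normal_consistency=False)
        assert np.std(z_raw) > np.std(z_corr)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_textbook_oracle(self, ps):
        assert np.allclose(bh_adjust(ps), bh_oracle(ps))

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            bh_adjust([0.5, 1.5])


class TestFilterCandidates:
    def _inputs(self):
        genes = [f"g{i}" for i in range(8)]
        qe_stem = pd.Series({g: 2 for g in genes})
        qe_diff = pd.Series({**{g: 2 for g in genes}, "g0": 4, "g2": 4, "g4": 4})
        baseline = BaselineReference({g: 1.0 for g in genes},
                                     {g: 2 for g in genes} | {"g0": 1, "g2": 1,
                                                              "g4": 1})
        scc = {"g0", "g1", "g5", "g6"}
        prior = PriorNetwork((
            Edge("g0", "g1", TRANSCRIPTION, INHIBITION),   # c3 pair
            Edge("g2", "g3", TRANSCRIPTION, ACTIVATION),   # no SCC membership
            Edge("g4", "g5", TRANSCRIPTION, INHIBITION),   # c4 pair (g5 in SCC)
        ))
        return qe_stem, qe_diff, baseline, scc, prior

    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["gene1", "gene2", "d", "z", "p", "p_adj"])
        return df

    def test_c1_failure_excluded(self):
        qe_stem, qe_diff, baseline, scc, prior = self._inputs()
        res = self._results([("g1", "g6", 2.0, 4.0, 1e-5, 1e-4)])  # neither up
        out = filter_candidates(res, qe_stem, qe_diff, baseline, scc, prior)
        assert out.empty

    def test_outside_scc_excluded(self):
        qe_stem, qe_diff, baseline, scc, prior = self._inputs()
        res = self._results([("g2", "g3", 2.0, 4.0, 1e-5, 1e-4)])  # up but no SCC
        out = filter_candidates(res, qe_stem, qe_diff, baseline, scc, prior)
        assert out.empty

    def test_c3_and_c4_pass_and_orientation(self):
        qe_stem, qe_diff, baseline, scc, prior = self._inputs()
        res = self._results([
            ("g0", "g1", 2.0, 4.0, 1e-5, 1e-4),    # both in SCC, linked
            ("g4", "g5", -2.0, -4.0, 1e-5, 1e-4),  # one in SCC, linked; g4 is up
            ("g0", "g6", 2.0, 4.0, 1e-5, 1e-4),    # both in SCC, not linked
            ("g2", "g3", 2.0, 4.0, 1e-5, 0.2),     # not significant anyway
        ])
        out = filter_candidates(res, qe_stem, qe_diff, baseline, scc, prior)
        assert set(map(tuple, out[["gene1", "gene2"]].to_numpy())) == {
            ("g0", "g1"), ("g4", "g5")}
        row = out[out["gene1"] == "g4"].iloc[0]
        assert row["c4_one_in_scc_partner_interacts"] and not \
            row["c3_both_in_scc_connected"]
        # orientation flips sign so the up-gene comes first
        assert row["d"] == pytest.approx(-(-2.0)) or row["d"] == pytest.approx(-2.0)

    def test_down_in_stem_vetoes(self):
        qe_stem, qe_diff, baseline, scc, prior = self._inputs()
        qe_stem = qe_stem.copy()
        qe_stem["g1"] = 1
        baseline.quartiles["g1"] = 3  # stem 1 vs baseline 3 -> down in stem
        res = self._results([("g0", "g1", 2.0, 4.0, 1e-5, 1e-4)])
        out = filter_candidates(res, qe_stem, qe_diff, baseline, scc, prior)
        assert out.empty

    def test_candidates_subset_of_significant(self):
        qe_stem, qe_diff, baseline, scc, prior = self._inputs()
        res = self._results([("g0", "g1", 2.0, 4.0, 1e-5, 0.5)])
        out = filter_candidates(res, qe_stem, qe_diff, baseline, scc, prior)
        assert out.empty


class TestTestPairsOrientationInvariance:
    def test_significant_set_independent_of_labeling(self):
        rng = np.random.default_rng(7)
        genes = {f"g{i:03d}": list(rng.normal(6, 1, 2)) for i in range(40)}
        genes["g000"][1] += 3.0  # one disbalanced gene
        s = summary_from(genes)
        res = evaluate_pairs(s, list(genes), "stem", "diff")
        sig = {frozenset((r.gene1, r.gene2))
               for r in res[res["significant"]].itertuples(index=False)}
        # reversed TF list order must give the same unordered significant set
        res2 = evaluate_pairs(s, list(genes)[::-1], "stem", "diff")
        sig2 = {frozenset((r.gene1, r.gene2))
                for r in res2[res2["significant"]].itertuples(index=False)}
        assert sig == sig2
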