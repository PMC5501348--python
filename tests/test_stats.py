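import numpy as np
import pandas as pd
import pytest

from eegfc.cohort import paper_cohort_fixture
from eegfc.stats import (
    GLOBAL_METRICS,
    biomarker_analysis,
    maxstat_correction,
    permutation_test,
    rank_regression,
    spearman,
    threshold_sweep,
)


class TestSpearman:
    def test_reference_cohort_values(self):
        t = paper_cohort_fixture()
        assert spearman(t.FMUE_Pre, t.FMUE_Post) == pytest.approx(0.89, abs=0.005)
        assert spearman(t.FMUE_Pre, t.dFMUE) == pytest.approx(0.22, abs=0.005)

    def test_reversed_order_gives_minus_one(self, rng):
        x = rng.standard_normal(20)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestRankRegression:
    def test_perfect_monotone_gives_one(self):
        x = np.arange(10.0)
        assert rank_regression(x, np.exp(x)) == pytest.approx(1.0)

    def test_equals_squared_spearman(self, rng):
        for _ in range(50):
            x, y = rng.standard_normal((2, 25))
            assert rank_regression(x, y) == pytest.approx(spearman(x, y) ** 2,
                                                          abs=1e-12)

    def test_reference_cohort_value(self):
        t = paper_cohort_fixture()
        assert rank_regression(t.FMUE_Pre, t.dFMUE) == pytest.approx(
            spearman(t.FMUE_Pre, t.dFMUE) ** 2, abs=1e-12)

    def test_null_expectation(self, rng):
        n = 30
        vals = [rank_regression(rng.standard_normal(n), rng.standard_normal(n))
                for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(1 / (n - 1), abs=0.01)


class TestPermutationTest:
    def test_monotone_pair_highly_significant(self):
        x = np.arange(10.0)
        obs, p = permutation_test(x, 2 * x + 1, B=10000, seed=0)
        assert obs == pytest.approx(1.0)
        assert p <= 0.001

    def test_deterministic_given_seed(self, rng):
        x, y = rng.standard_normal((2, 30))
        assert permutation_test(x, y, B=500, seed=42) == \
            permutation_test(x, y, B=500, seed=42)

    def test_permutation_invariant_statistic_gives_p_one(self, rng):
        x = rng.standard_normal(20)
        stat = lambda a, b: float(np.mean(a))  # ignores the permuted outcome
        _, p = permutation_test(x, rng.standard_normal(20), statistic=stat,
                                B=200, seed=0)
        assert p == 1.0

    def test_rank_r2_mode_matches_squared_spearman(self, rng):
        x, y = rng.standard_normal((2, 25))
        obs, _ = permutation_test(x, y, statistic="rank_r2", B=100, seed=0)
        assert obs == pytest.approx(spearman(x, y) ** 2, abs=1e-12)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            permutation_test(rng.random(10), rng.random(10), B=50)


class TestMaxstatCorrection:
    def test_single_electrode_equals_uncorrected(self, rng):
        x = rng.standard_normal((200, 1))
        obs = np.array([0.4])
        corrected = maxstat_correction(obs, x)
        uncorrected = (1 + (np.abs(x[:, 0]) >= 0.4 - 1e-12).sum()) / 201
        assert corrected[0] == pytest.approx(uncorrected)

    def test_correction_is_conservative_for_nulls(self, rng):
        stronger = 0
        for _ in range(30):
            perm = rng.standard_normal((300, 58))
            obs = rng.standard_normal(58)
            corr = maxstat_correction(obs, perm)
            uncorr = ((1 + (np.abs(perm) >= np.abs(obs)[None, :] - 1e-12)
                       .sum(axis=0)) / 301)
            assert np.all(corr >= uncorr - 1e-12)
            stronger += corr.min() > uncorr.min()
        assert stronger >= 25

    def test_planted_node_effect_detected(self, rng):
        """One electrode with a strong monotone relation among 57 nulls
        survives family-wise correction at n=30."""
        n, B = 30, 1000
        y = rng.standard_normal(n)
        data = rng.standard_normal((58, n))
        data[17] = y + 0.35 * rng.standard_normal(n)  # strong planted effect
        obs = np.array([spearman(data[e], y) for e in range(58)])
        perm = np.empty((B, 58))
        prng = np.random.default_rng(1)
        for b in range(B):  # one shared permutation stream for all electrodes
            yp = prng.permutation(y)
            perm[b] = [spearman(data[e], yp) for e in range(58)]
        p = maxstat_correction(obs, perm)
        assert p[17] < 0.05


def _synthetic_metrics(rng, subjects, bands=("6.25-12.5", "12.5-25", "25-50")):
    rows = []
    for s in subjects:
        for sess in ("pre", "post"):
            for band in bands:
                for metric in GLOBAL_METRICS:
                    rows.append({"subject": s, "session": sess, "band": band,
                                 "metric": metric, "value": rng.random()})
    return pd.DataFrame(rows)


class TestBiomarkerAnalysis:
    @pytest.fixture
    def cohort(self):
        t = paper_cohort_fixture()
        t["Patient"] = t["Patient"].astype(str).radd("S")
        return t

    def test_full_grid_shape_and_reproducibility(self, rng, cohort):
        metrics = _synthetic_metrics(rng, cohort["Patient"])
        res1 = biomarker_analysis(metrics, cohort, B=200, seed=3)
        res2 = biomarker_analysis(metrics, cohort, B=200, seed=3)
        assert len(res1) == 5 * 3 * 2  # metrics x bands x groups
        assert res1.groupby(["metric", "band", "group"]).size().eq(1).all()
        pd.testing.assert_frame_equal(res1, res2)
        assert (res1[res1.group == "cortex"]["n_subjects"] == 17).all()
        assert (res1[res1.group == "all"]["n_subjects"] == 30).all()

    def test_degenerate_cells_reported_not_raised(self, rng, cohort):
        metrics = _synthetic_metrics(rng, cohort["Patient"])
        metrics["value"] = 0.5  # post == pre everywhere -> constant changes
        res = biomarker_analysis(metrics, cohort, B=200, seed=0)
        assert res["status"].str.startswith("degenerate").all()
        assert res["p_perm"].isna().all()

    def test_initial_vs_change_uses_rank_r2(self, rng, cohort):
        metrics = _synthetic_metrics(rng, cohort["Patient"])
        res = biomarker_analysis(metrics, cohort, mode="initial_vs_change",
                                 B=200, seed=1)
        assert (res["statistic_kind"] == "rank_R2").all()
        assert res["value"].between(0, 1).all()


class TestThresholdSweep:
    def _matrices(self, rng, n_subj=24, planted=True):
        """Per-subject pre/post matrices with a sparse planted effect: a few
        unaffected-hemisphere entries far above the bulk, removed post in
        proportion to the outcome."""
        from eegfc.connectivity import DependenceMatrix
        from eegfc.montage import CHANNELS_58, default_hemisphere_map
        hmap = default_hemisphere_map()
        uidx = [CHANNELS_58.index(l) for l in hmap.unaffected_set]
        mats, cohort_rows = {}, []
        for k in range(n_subj):
            dfmue = round(22 * k / (n_subj - 1))
            ring = [(uidx[i], uidx[(i + 1) % 15]) for i in range(15)]
            removed = int(round(len(ring) * dfmue / 30)) if planted else 0
            for sess, edges in (("pre", ring), ("post", ring[removed:])):
                # session-independent bulk, so denser thresholds admit more
                # churn and dilute the planted change
                v = rng.uniform(0.3, 0.5, size=(58, 58))
                v = (v + v.T) / 2
                np.fill_diagonal(v, 0.0)
                for i, j in edges:
                    v[i, j] = v[j, i] = 0.9
                mats[(f"S{k}", sess, "12.5-25")] = DependenceMatrix(
                    f"S{k}", sess, "12.5-25", v, CHANNELS_58, 1)
            cohort_rows.append({"Patient": f"S{k}", "Location": "Cortex",
                                "dFMUE": dfmue})
        return mats, pd.DataFrame(cohort_rows)

    def test_sparse_planted_effect_selects_sparsest_threshold(self, rng):
        mats, cohort = self._matrices(rng)
        grid = np.round(np.arange(0.05, 0.501, 0.05), 2)
        table, t_sel = threshold_sweep(mats, cohort, grid)
        assert t_sel == pytest.approx(0.05)
        assert set(table["t"].unique()) == set(grid)

    def test_single_threshold_selected(self, rng):
        mats, cohort = self._matrices(rng, n_subj=6)
        _, t_sel = threshold_sweep(mats, cohort, [0.1])
        assert t_sel == 0.1

    def test_empty_grid_rejected(self, rng):
        mats, cohort = self._matrices(rng, n_subj=6)
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(mats, cohort, [])
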