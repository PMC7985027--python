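import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import pearsonr

from vtstain import concordance as conc
from vtstain import synthetic


class TestMonotonicEffect:
    def test_uniform_simplex_midpoint(self):
        assert conc.monotonic_effect(2, 1.0, np.full(4, 0.25)) == pytest.approx(0.5)

    def test_zero_at_origin_full_at_top(self):
        zeta = np.array([0.4, 0.3, 0.2, 0.1])
        assert conc.monotonic_effect(0, 7.3, zeta) == 0.0
        assert conc.monotonic_effect(4, 7.3, zeta) == pytest.approx(7.3)

    def test_direct_summation(self):
        assert conc.monotonic_effect(1, 2.0, np.array([0.7, 0.1, 0.1, 0.1])) == pytest.approx(1.4)

    def test_nondecreasing_for_positive_b(self):
        zeta = np.array([0.1, 0.5, 0.15, 0.25])
        vals = [conc.monotonic_effect(x, 3.0, zeta) for x in range(5)]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))

    def test_out_of_range_stage_rejected(self):
        with pytest.raises(ValueError):
            conc.monotonic_effect(5, 1.0, np.full(4, 0.25))


class TestCumulativeLogit:
    def test_symmetric_cutpoints_mirror_probabilities(self):
        kappa = np.array([-2.0, -0.5, 0.5, 2.0])
        p = np.exp([conc.cumulative_logit_logpmf(k, 0.0, kappa) for k in range(5)])
        assert p[0] == pytest.approx(p[4])
        assert p[1] == pytest.approx(p[3])

    def test_normalization(self, rng):
        for _ in range(10):
            kappa = np.sort(rng.normal(0, 2, 4))
            if (np.diff(kappa) <= 0).any():
                continue
            eta = rng.normal(0, 3)
            total = sum(np.exp(conc.cumulative_logit_logpmf(k, eta, kappa))
                        for k in range(5))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_logistic_cdf_closed_form(self):
        kappa = np.array([-1.5, -0.5, 0.5, 1.5])
        assert np.exp(conc.cumulative_logit_logpmf(0, 0.0, kappa)) == pytest.approx(
            expit(-1.5), abs=1e-12)

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            conc.cumulative_logit_logpmf(0, 0.0, np.array([0.5, -0.5, 1.0, 2.0]))


class TestIntervalHandling:
    def _obs(self, low, high):
        return pd.DataFrame({"case_id": ["c"], "rater_id": ["r"], "modality": ["real"],
                             "test_index": [1], "stage_low": [low], "stage_high": [high]})

    def test_interval_bounds(self):
        obs = self._obs(2, 3)
        assert conc.interval_bound(obs, "upper")["stage"].iloc[0] == 3
        assert conc.interval_bound(obs, "lower")["stage"].iloc[0] == 2

    def test_point_report_unchanged_either_bound(self):
        obs = self._obs(4, 4)
        for bound in ("upper", "lower"):
            assert conc.interval_bound(obs, bound)["stage"].iloc[0] == 4

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            conc.interval_bound(self._obs(3, 2), "upper")


class TestIqrFilter:
    def _real(self, case_stage_pairs):
        rows = [{"case_id": c, "stage": s} for c, stages in case_stage_pairs
                for s in stages]
        return pd.DataFrame(rows)

    def test_unanimous_case_retained(self):
        assert conc.iqr_filter(self._real([("a", [3, 3, 3, 3])]), 0.3) == ["a"]

    def test_linear_interpolation_quantiles_exclude(self):
        # (2,3,3,4): q25 = 2.75, q75 = 3.25 -> IQR 0.5 > 0.3
        assert conc.iqr_filter(self._real([("a", [2, 3, 3, 4])]), 0.3) == []
        assert conc.iqr_filter(self._real([("a", [2, 3, 3, 4])]), np.inf) == ["a"]


class TestBuildDesign:
    def test_row_count_and_pairing(self, staging_small):
        staging, truth = staging_small
        design = conc.build_design(staging, "upper")
        # 60 cases x 4 raters x 2 real tests
        assert len(design) == 60 * 4 * 2
        assert set(design.columns) == {"case_id", "rater_id", "test", "x", "y"}
        assert set(design["test"]) == {0, 1}

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["case_id", "rater_id", "modality",
                                      "test_index", "stage_low", "stage_high"])
        assert conc.build_design(empty, "upper").empty

    def test_missing_virtual_row_dropped_others_intact(self, staging_small):
        staging, _ = staging_small
        drop = (staging["case_id"] == "C0000") & (staging["rater_id"] == "R1") \
            & (staging["modality"] == "virtual")
        design = conc.build_design(staging[~drop], "upper")
        assert len(design) == 60 * 4 * 2 - 2
        assert not ((design["case_id"] == "C0000") & (design["rater_id"] == "R1")).any()


class TestSpearmanBootstrap:
    def test_monotone_map_gives_unit_rho(self):
        x = np.arange(10.0)
        res = conc.spearman_bootstrap(x, np.exp(x), n_boot=200, seed=0)
        assert res["rho"] == pytest.approx(1.0)
        assert res["ci_low"] == pytest.approx(1.0)
        assert res["ci_high"] == pytest.approx(1.0)
        assert res["non_inferior"]

    def test_antitone_gives_minus_one(self):
        x = np.arange(10.0)
        assert conc.spearman_bootstrap(x, -x, n_boot=100, seed=0)["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        # brute force: average ranks then Pearson
        def avg_rank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            sorted_v = v[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks
        oracle = pearsonr(avg_rank(x), avg_rank(y)).statistic
        res = conc.spearman_bootstrap(x, y, n_boot=10, seed=0, cutoff=None)
        assert res["rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            conc.spearman_bootstrap(np.ones(5), np.arange(5.0), n_boot=10, seed=0)

    def test_group_resampling_reproducible(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        g = np.repeat(np.arange(10), 3)
        r1 = conc.spearman_bootstrap(x, y, n_boot=200, seed=4, groups=g)
        r2 = conc.spearman_bootstrap(x, y, n_boot=200, seed=4, groups=g)
        assert r1 == r2


class TestReliability:
    def test_identical_tests_unit_rho(self):
        rows = []
        for case in range(10):
            for rater in ("R1", "R2"):
                for t in (1, 2):
                    rows.append({"case_id": case, "rater_id": rater,
                                 "test_index": t, "stage": case % 5})
        res = conc.test_retest(pd.DataFrame(rows), n_boot=50, seed=0)
        assert (res["rho"] == 1.0).all()

    def test_interrater_matrix_identical_raters(self):
        rows = [{"case_id": c, "rater_id": r, "stage": c % 5}
                for c in range(12) for r in ("R1", "R2", "R3")]
        mat, mean_off = conc.interrater_matrix(pd.DataFrame(rows))
        assert np.allclose(mat.to_numpy(), 1.0)
        assert mean_off == pytest.approx(1.0)

    def test_interrater_matrix_symmetric_unit_diagonal(self, staging_small):
        staging, _ = staging_small
        pt = conc.interval_bound(staging, "upper")
        virt = pt[(pt["modality"] == "virtual") & (pt["test_index"] == 1)]
        mat, _ = conc.interrater_matrix(virt)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)


class TestKappa:
    def test_hand_computed_contingency(self):
        # p_o = 0.85, p_e = 0.25*0.30 + 0.75*0.70 = 0.60 -> kappa = 0.625
        assert conc.cohen_kappa([[20, 5], [10, 65]]) == pytest.approx(0.625)

    def test_perfect_agreement(self):
        rows_r, rows_v = [], []
        for c in range(20):
            stage = 4 if c < 6 else c % 4
            for r in ("R1", "R2"):
                rows_r.append({"case_id": c, "rater_id": r, "stage": stage})
                rows_v.append({"case_id": c, "rater_id": r, "stage": stage})
        res = conc.advanced_fibrosis_agreement(pd.DataFrame(rows_r),
                                               pd.DataFrame(rows_v), n_boot=50)
        assert res["kappa"] == pytest.approx(1.0)
        assert res["mean_sensitivity"] == pytest.approx(1.0)
        assert (res["sensitivity_per_rater"]["sensitivity"] == 1.0).all()

    def test_no_unanimous_f4_reported_as_undefined(self):
        rows = [{"case_id": c, "rater_id": r, "stage": 2}
                for c in range(5) for r in ("R1", "R2")]
        res = conc.advanced_fibrosis_agreement(pd.DataFrame(rows),
                                               pd.DataFrame(rows), n_boot=10)
        assert res["unanimous_f4_cases"] == []
        assert np.isnan(res["mean_sensitivity"])

    def test_independent_labels_kappa_near_zero(self):
        """With independent real/virtual labels the kappa CI covers 0 in
        roughly 95% of replicates."""
        rng = np.random.default_rng(5)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            n = 120
            lab_r = rng.uniform(size=n) < 0.3
            lab_v = rng.uniform(size=n) < 0.3
            rows_r = [{"case_id": i, "rater_id": "R1", "stage": 4 if lr else 2}
                      for i, lr in enumerate(lab_r)]
            rows_v = [{"case_id": i, "rater_id": "R1", "stage": 4 if lv else 2}
                      for i, lv in enumerate(lab_v)]
            res = conc.advanced_fibrosis_agreement(pd.DataFrame(rows_r),
                                                   pd.DataFrame(rows_v), n_boot=300,
                                                   seed=int(rng.integers(2**31)))
            lo, hi = res["kappa_ci"]
            covered += int(lo <= 0.0 <= hi)
        assert covered / n_rep >= 0.85


@pytest.fixture(scope="module")
def fitted():
    staging, truth = synthetic.simulate_rater_stages(
        synthetic.RaterSimSpec(n_cases=80, seed=21))
    design = conc.build_design(staging, "upper")
    post = conc.fit_concordance_model(design, chains=2, warmup=800, draws=800,
                                      seed=3, check_convergence=False)
    return post, truth, design


class TestModelFit:

    def test_posterior_invariants(self, fitted):
        post, _, _ = fitted
        assert (np.diff(post.kappa, axis=-1) > 0).all()
        assert np.allclose(post.zeta.sum(axis=-1), 1.0)
        assert (post.zeta >= 0).all()
        assert (post.sd_u > 0).all()

    def test_diagnostics_present(self, fitted):
        post, _, _ = fitted
        assert "max_rhat" in post.diagnostics
        assert post.diagnostics["min_ess"] > 0

    def test_single_level_response_rejected(self):
        design = pd.DataFrame({"case_id": ["a", "b"] * 4, "rater_id": ["r1", "r2"] * 4,
                               "test": [0] * 8, "x": [1, 2] * 4, "y": [2] * 8})
        with pytest.raises(ValueError, match="single"):
            conc.fit_concordance_model(design, warmup=10, draws=10)

    def test_bias_adjustment_bounded_and_new_case_guard(self, fitted):
        post, _, design = fitted
        adj = conc.bias_adjusted_stage(post, design)
        assert ((adj >= 0) & (adj <= 4)).all()
        novel = design.head(2).copy()
        novel["case_id"] = "NOPE"
        with pytest.raises(KeyError):
            conc.bias_adjusted_stage(post, novel)

    def test_bias_adjustment_noop_when_raters_identical(self, fitted):
        """When every draw carries identical rater effects, neutralizing the
        rater terms is exactly a no-op: adjusted equals the raw expectation."""
        import dataclasses
        post0, _, design = fitted
        post = dataclasses.replace(
            post0,
            alpha=np.repeat(post0.alpha.mean(axis=-1, keepdims=True), post0.alpha.shape[-1], axis=-1),
            b_offset=np.repeat(post0.b_offset.mean(axis=-1, keepdims=True), post0.b_offset.shape[-1], axis=-1),
        )
        adjusted = conc.bias_adjusted_stage(post, design)
        # raw expectation computed with each row's own (now identical) effects
        rmap = {r: i for i, r in enumerate(post.raters)}
        cmap = {c: i for i, c in enumerate(post.cases)}
        kappa = post.flat("kappa"); b = post.flat("b")
        db = post.flat("b_offset"); al = post.flat("alpha")
        zeta = post.flat("zeta"); u = post.flat("u")
        cum = np.concatenate([np.zeros((kappa.shape[0], 1)),
                              np.cumsum(zeta, axis=1)], axis=1)
        x = design["x"].to_numpy(); test = design["test"].to_numpy(float)
        ridx = design["rater_id"].map(rmap).to_numpy()
        cidx = design["case_id"].map(cmap).to_numpy()
        eta = (al[:, ridx] + (b[:, None] + db[:, ridx]) * cum[:, x]
               + u[:, cidx, 0] + u[:, cidx, 1] * test)
        edges = np.concatenate([np.full((kappa.shape[0], 1), -np.inf), kappa,
                                np.full((kappa.shape[0], 1), np.inf)], axis=1)
        cdf = expit(edges[:, :, None] - eta[:, None, :])
        probs = np.diff(cdf, axis=1)
        raw = np.einsum("k,dkn->n", np.arange(5.0), probs) / kappa.shape[0]
        assert np.abs(adjusted - raw).max() < 1e-9
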