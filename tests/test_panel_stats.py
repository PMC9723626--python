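"""Persistence windows, normalization, correlations, Fisher, stepwise AIC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rrnscape import (
    fisher_enrichment,
    normalize_per_kb,
    size_factors,
    stepwise_model,
    windowed_persistence,
)
from rrnscape.synthetic_data import simulate_model_features


class TestWindowedPersistence:
    def test_constant_track_unchanged(self):
        out = windowed_persistence(np.ones(200))
        assert np.allclose(out, 1.0)

    def test_single_zero_dip_depth(self):
        v = np.ones(301)
        v[150] = 0.0
        out = windowed_persistence(v, window=81)
        assert out[150] == pytest.approx(1 - 1 / 81)
        assert out[0] == 1.0

    def test_bounded_by_raw_extremes(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 500)
        out = windowed_persistence(v)
        assert out.min() >= v.min() and out.max() <= v.max()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 20).map(lambda k: 2 * k + 1))
    def test_matches_brute_force_mean(self, seed, window):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, int(rng.integers(1, 120)))
        out = windowed_persistence(v, window)
        half = window // 2
        brute = [
            np.mean(v[max(i - half, 0) : min(i + half + 1, len(v))])
            for i in range(len(v))
        ]
        assert np.allclose(out, brute)


class TestSizeFactors:
    def test_closed_form_doubling(self):
        a = pd.DataFrame({"A": [100, 200, 50], "B": [200, 400, 100]})
        f = size_factors(a)
        # reference = geometric mean; ratios are 2^-1/2 and 2^+1/2
        assert f["A"] == pytest.approx(2 ** -0.5)
        assert f["B"] == pytest.approx(2 ** 0.5)

    def test_identical_samples_unit_factors(self):
        a = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]})
        assert np.allclose(size_factors(a), 1.0)

    def test_all_zero_rows_ignored(self):
        a = pd.DataFrame({"A": [10, 0, 30], "B": [10, 0, 30]})
        assert np.allclose(size_factors(a), 1.0)

    def test_global_scaling_cancels_and_per_sample_scaling_shows(self):
        # the gene-wise geometric-mean reference absorbs any global factor,
        # while a per-sample depth change moves that sample's factor
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.integers(1, 1000, (50, 4)))
        assert np.allclose(size_factors(3 * a), size_factors(a))
        b = a.copy()
        b[0] = 2 * b[0]
        ratio = size_factors(b) / size_factors(a)
        assert ratio[0] / ratio[1] == pytest.approx(2.0)


class TestNormalizePerKb:
    def test_formula_instantiation(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        out = normalize_per_kb(
            counts, {"g": 1000}, pd.Series({"s": 1.0}), pseudocount=1
        )
        assert out.loc["g", "s"] == pytest.approx(np.log2(101))

    def test_doubling_length_halves_prelog_value(self):
        counts = pd.DataFrame({"s": [100, 100]}, index=["g1", "g2"])
        out = normalize_per_kb(
            counts, {"g1": 1000, "g2": 2000}, pd.Series({"s": 1.0}), pseudocount=0
        )
        assert out.loc["g1", "s"] - out.loc["g2", "s"] == pytest.approx(1.0)

    def test_rank_recovery_in_low_dispersion_limit(self, ancestor_small):
        from rrnscape import ExpressionSpec, emit_expression

        genome, _, _ = ancestor_small
        counts, truth = emit_expression(
            genome,
            ExpressionSpec(
                baseline=5000.0, distance_decay=1e-5, dispersion=0.001, seed=9
            ),
        )
        norm = normalize_per_kb(counts, truth.length_bp.to_dict())
        mean_norm = norm.mean(axis=1)
        per_kb_truth = truth.expected_mean / (truth.length_bp / 1000)
        # arm genes have distinct expected means (distance decay); central
        # genes are exactly tied, which caps any rank correlation
        arm = truth.index[~truth.in_central]
        rho = stats.spearmanr(mean_norm.loc[arm], per_kb_truth.loc[arm]).statistic
        assert rho > 0.95


class TestFisher:
    def test_odds_ratio_arithmetic(self):
        odds, _ = fisher_enrichment(10, 5, 2, 8)
        assert odds == pytest.approx(8.0)

    def test_flat_table(self):
        odds, p = fisher_enrichment(5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_enrichment(a, b, c, d)
            # enumerate all tables with the same margins
            n = a + b + c + d
            row1, col1 = a + b, a + c
            probs = {}
            for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
                probs[x] = stats.hypergeom.pmf(x, n, row1, col1)
            p_obs = probs[a]
            p_brute = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(p_brute, rel=1e-6)


class TestStepwiseModel:
    def test_exact_recovery_in_noiseless_limit(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(0, 1, 80)
        x2 = rng.normal(0, 1, 80)
        y = 3.0 + 0.9 * x1 + 2.0 * x2
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = stepwise_model(df, response="y")
        assert set(fit.selected) == {"x1", "x2"}
        assert fit.coefficients["intercept"] == pytest.approx(3.0, abs=1e-8)
        assert fit.coefficients["x1"] == pytest.approx(0.9, abs=1e-8)
        assert fit.r_pred_obs == pytest.approx(1.0)

    def test_signal_always_selected_over_decoys(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 100
            x1 = rng.normal(0, 1, n)
            decoys = {f"d{i}": rng.normal(0, 1, n) for i in range(5)}
            y = 3 + 0.9 * x1 + rng.normal(0, 0.5, n)
            df = pd.DataFrame({"y": y, "x1": x1, **decoys})
            fit = stepwise_model(df, response="y")
            if "x1" in fit.selected:
                hits += 1
        assert hits == 20

    def test_forward_and_backward_agree_on_orthogonal_design(self):
        n = 64
        # orthogonal columns from a Hadamard-like construction
        base = np.array([1.0, -1.0])
        x1 = np.tile(np.repeat(base, 1), n // 2)
        x2 = np.tile(np.repeat(base, 2), n // 4)
        x3 = np.tile(np.repeat(base, 4), n // 8)
        rng = np.random.default_rng(5)
        y = 2 * x1 + 1.5 * x2 + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})
        fit = stepwise_model(df, response="y")
        assert set(fit.selected_forward) == set(fit.selected_backward)

    def test_collinear_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(0, 1, 50)
        df = pd.DataFrame(
            {"y": x1 + rng.normal(0, 0.1, 50), "x1": x1, "x1copy": 2 * x1}
        )
        with pytest.warns(UserWarning, match="collinear"):
            fit = stepwise_model(df, response="y")
        assert "x1copy" not in fit.selected

    def test_too_few_observations_is_error(self):
        df = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0], "a": [1.0, 0, 0], "b": [0, 1.0, 0], "c": [0, 0, 1.0]}
        )
        with pytest.raises(ValueError, match="too small"):
            stepwise_model(df, response="y")

    def test_selected_aic_never_above_null_model(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = simulate_model_features(60, seed=0)
            fit = stepwise_model(df)
        y = df.core_region_size.to_numpy()
        n = len(y)
        rss0 = float(((y - y.mean()) ** 2).sum())
        aic_null = n * np.log(rss0 / n) + 2 * 2
        assert fit.aic <= aic_null
        assert fit.aic == min(fit.aic_forward, fit.aic_backward)

    def test_generative_predictors_dominate_feature_panels(self):
        true = {"central_size", "chromosome_size", "d_max_rrn_ori", "n_rrn_genes"}
        ok = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(25):
                fit = stepwise_model(simulate_model_features(60, seed=1000 + s))
                if true <= set(fit.selected):
                    ok += 1
        assert ok >= 22
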