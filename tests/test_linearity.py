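"""Tests of the combination regression and its aggregation."""

import numpy as np
import pandas as pd
import pytest

from mixlin import (CollinearityError, DataError, DesignError, MixtureDesign,
                    QuantMatrix, enumerate_combinations, fit_all,
                    fit_combination, fit_rescaled, standardize)
from mixlin.matrix import infer_sample_info
from conftest import make_matrix, ols_oracle


def _design(reps: int) -> MixtureDesign:
    return MixtureDesign.seqc(n_replicates=reps)


# ---------------------------------------------------------------------------
# combination enumeration
# ---------------------------------------------------------------------------

def test_four_replicates_yield_64_models():
    combos = enumerate_combinations(_design(4), "C")
    assert len(combos) == 64
    assert len({tuple(c.items()) for c in combos}) == 64


def test_fixing_one_pure_replicate_selects_16_models():
    combos = enumerate_combinations(_design(4), "C")
    assert sum(1 for c in combos if c["A"] == 2) == 16


def test_degenerate_and_small_products():
    assert len(enumerate_combinations(_design(1), "C")) == 1
    assert len(enumerate_combinations(_design(2), "C")) == 8


def test_enumeration_is_lexicographic():
    combos = enumerate_combinations(_design(2), "C")
    assert combos[0] == {"A": 1, "B": 1, "C": 1}
    assert combos[1] == {"A": 1, "B": 1, "C": 2}
    assert combos[-1] == {"A": 2, "B": 2, "C": 2}


def test_unknown_mixture_type_rejected():
    with pytest.raises(DesignError):
        enumerate_combinations(_design(4), "Z")


# ---------------------------------------------------------------------------
# single fits
# ---------------------------------------------------------------------------

def test_exactly_representable_targets():
    rng = np.random.default_rng(2)
    A = rng.gamma(2.0, 10.0, size=50)
    B = rng.gamma(2.0, 10.0, size=50)
    fit = fit_combination(A, {"A": A, "B": B})
    assert fit.coefficients["A"] == pytest.approx(1.0, abs=1e-9)
    assert fit.coefficients["B"] == pytest.approx(0.0, abs=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-7)

    y = 0.75 * A + 0.25 * B
    fit = fit_combination(y, {"A": A, "B": B})
    assert fit.coefficients["A"] == pytest.approx(0.75, abs=1e-9)
    assert fit.coefficients["B"] == pytest.approx(0.25, abs=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-7)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_residuals_are_observed_minus_fitted():
    rng = np.random.default_rng(3)
    A, B = rng.gamma(2, 10, 30), rng.gamma(2, 10, 30)
    y = 0.6 * A + 0.4 * B + rng.normal(0, 5, 30)
    fit = fit_combination(y, {"A": A, "B": B})
    np.testing.assert_array_equal(fit.residuals, y - fit.fitted)


def test_perturbed_small_instance_matches_oracle():
    """A + B is constant here, so the instance is only identifiable without
    an intercept; both routes must agree on the no-intercept solution."""
    A = np.array([1.0, 2.0, 3.0, 4.0])
    B = np.array([4.0, 3.0, 2.0, 1.0])
    y = np.array([2.0, 2.0, 2.0, 2.0]) + np.array([0.01, -0.02, 0.005, 0.01])
    fit = fit_combination(y, {"A": A, "B": B}, with_intercept=False)
    _, coefs = ols_oracle(y, [A, B], with_intercept=False)
    assert fit.coefficients["A"] == pytest.approx(coefs[0], abs=1e-6)
    assert fit.coefficients["B"] == pytest.approx(coefs[1], abs=1e-6)
    with pytest.raises(CollinearityError):
        fit_combination(y, {"A": A, "B": B})


def test_randomized_instances_match_oracle():
    """Property: OLS agrees with the independent normal-equations solver."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        A = rng.gamma(2.0, 10.0, size=10)
        B = rng.gamma(2.0, 10.0, size=10)
        y = rng.uniform(0, 1) * A + rng.uniform(0, 1) * B + rng.normal(0, 2, 10)
        fit = fit_combination(y, {"A": A, "B": B})
        icpt, coefs = ols_oracle(y, [A, B])
        np.testing.assert_allclose([fit.intercept, *fit.coefficients.values()],
                                   [icpt, *coefs], rtol=1e-6, atol=1e-6)


def test_collinear_predictors_rejected():
    A = np.arange(1.0, 11.0)
    with pytest.raises(CollinearityError):
        fit_combination(2 * A, {"A": A, "B": 3 * A})


def test_length_mismatch_and_too_few_features():
    with pytest.raises(ValueError):
        fit_combination(np.ones(5), {"A": np.ones(5), "B": np.ones(4)})
    with pytest.raises(DataError):
        fit_combination(np.arange(3.0), {"A": np.arange(3.0) ** 2,
                                         "B": np.arange(3.0) ** 3})


# ---------------------------------------------------------------------------
# rescaled model
# ---------------------------------------------------------------------------

def test_standardize_moments_and_degenerate():
    rng = np.random.default_rng(4)
    v = rng.gamma(3, 2, 100)
    s = standardize(v)
    assert s.mean() == pytest.approx(0.0, abs=1e-9)
    assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        standardize(np.full(10, 3.0))


def test_rescaled_perfect_fit_has_zero_residuals():
    rng = np.random.default_rng(5)
    A, B = rng.gamma(2, 10, 40), rng.gamma(2, 10, 40)
    fit = fit_rescaled(0.75 * A + 0.25 * B, {"A": A, "B": B})
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)


def test_rescaled_coefficients_relate_by_sd_ratio():
    """Standardized coefficients equal raw coefficients times sd(x)/sd(y)."""
    A = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
    B = np.array([5.0, 3.0, 8.0, 1.0, 9.0])
    y = 0.6 * A + 0.4 * B + np.array([0.1, -0.2, 0.0, 0.3, -0.1])
    raw = fit_combination(y, {"A": A, "B": B})
    resc = fit_rescaled(y, {"A": A, "B": B})
    sd_y = y.std(ddof=1)
    assert resc.coefficients["A"] == pytest.approx(
        raw.coefficients["A"] * A.std(ddof=1) / sd_y, rel=1e-9)
    assert resc.coefficients["B"] == pytest.approx(
        raw.coefficients["B"] * B.std(ddof=1) / sd_y, rel=1e-9)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_fit_all_recovers_design_weights(small_truth, small_counts):
    agg = fit_all(small_counts, small_truth.design, "C")
    assert agg.n_combinations == 64
    assert agg.coef_mean["A"] == pytest.approx(0.75, abs=1e-9)
    assert agg.coef_mean["B"] == pytest.approx(0.25, abs=1e-9)
    assert agg.intercept_mean == pytest.approx(0.0, abs=1e-6)
    for lo, hi in agg.coef_interval.values():
        assert hi - lo < 1e-9


def test_fit_all_is_linear_in_the_mixture_column(small_truth, small_counts):
    scaled_values = small_counts.values.copy()
    for sid, info in small_counts.sample_info.items():
        if info.sample_type == "C":
            scaled_values[sid] *= 0.5
    scaled = QuantMatrix(values=scaled_values,
                         sample_info=dict(small_counts.sample_info), unit="count")
    agg = fit_all(scaled, small_truth.design, "C")
    assert agg.coef_mean["A"] == pytest.approx(0.375, abs=1e-9)
    assert agg.coef_mean["B"] == pytest.approx(0.125, abs=1e-9)


def test_two_replicates_give_eight_combinations():
    rng = np.random.default_rng(6)
    cols = {}
    for t in ("A", "B", "C"):
        for r in (1, 2):
            cols[f"{t}_{r}"] = rng.gamma(2, 10, 30)
    m = make_matrix(cols)
    design = MixtureDesign(pure_types=("A", "B"),
                           mixtures={"C": {"A": 0.75, "B": 0.25}},
                           replicates={"A": 2, "B": 2, "C": 2})
    assert fit_all(m, design, "C").n_combinations == 8


def test_all_zero_features_are_filtered(small_truth, small_counts):
    values = small_counts.values.copy()
    values.iloc[0] = 0.0
    m = QuantMatrix(values=values, sample_info=dict(small_counts.sample_info),
                    unit="count")
    agg = fit_all(m, small_truth.design, "C")
    assert small_counts.feature_ids[0] not in agg.feature_ids
    assert len(agg.feature_ids) == m.n_features - 1


def test_feature_order_permutation_permutes_outputs(small_truth, small_counts):
    perm = np.random.default_rng(7).permutation(small_counts.n_features)
    shuffled = QuantMatrix(values=small_counts.values.iloc[perm],
                           sample_info=dict(small_counts.sample_info),
                           unit="count")
    a1 = fit_all(small_counts, small_truth.design, "C")
    a2 = fit_all(shuffled, small_truth.design, "C")
    assert a2.coef_mean == pytest.approx(a1.coef_mean)
    lookup = dict(zip(a1.feature_ids, a1.mean_fitted))
    np.testing.assert_allclose(a2.mean_fitted,
                               [lookup[f] for f in a2.feature_ids], rtol=1e-12)


def test_missing_replicates_rejected(small_truth, small_counts):
    keep = [s for s in small_counts.sample_ids if s != "C_3"]
    m = QuantMatrix(values=small_counts.values[keep],
                    sample_info={s: small_counts.sample_info[s] for s in keep},
                    unit="count")
    with pytest.raises(DataError):
        fit_all(m, small_truth.design, "C")


def test_depth_confound_and_tpm_restoration(small_truth, small_counts,
                                            small_lengths):
    """Scaling the mixture sample's depth by k scales both coefficients by k
    on noiseless counts; converting the same matrix to TPM removes the
    confound and restores the design weights."""
    from mixlin import counts_to_tpm

    k = 0.5
    values = small_counts.values.copy()
    info = {}
    for sid, si in small_counts.sample_info.items():
        if si.sample_type == "C":
            values[sid] *= k
            info[sid] = type(si)(si.sample_type, si.replicate,
                                 (si.library_size or 0) * k)
        else:
            info[sid] = si
    scaled = QuantMatrix(values=values, sample_info=info, unit="count")
    agg = fit_all(scaled, small_truth.design, "C")
    assert agg.coef_mean["A"] == pytest.approx(k * 0.75, abs=1e-9)
    assert agg.coef_mean["B"] == pytest.approx(k * 0.25, abs=1e-9)

    tpm = counts_to_tpm(scaled, small_lengths)
    agg_tpm = fit_all(tpm, small_truth.design, "C")
    assert agg_tpm.coef_mean["A"] == pytest.approx(0.75, abs=1e-9)
    assert agg_tpm.coef_mean["B"] == pytest.approx(0.25, abs=1e-9)
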