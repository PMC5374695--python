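"""Tests of the rank-concordance, residual-curve, profiling and ranking ops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mixlin import (GeneratorConfig, concordance_constructed,
                    concordance_fitted, counts_to_tpm, distribution_profile,
                    evaluate_units, fit_all, generate_truth, log_transform,
                    normalized_ranks, pooled_threshold_grid, render_counts,
                    replicate_mean, roc_like, summarize_methods, summary_table)
from conftest import make_matrix, spearman_oracle


# ---------------------------------------------------------------------------
# normalized ranks & concordance
# ---------------------------------------------------------------------------

def test_normalized_rank_worked_examples():
    np.testing.assert_allclose(normalized_ranks([10, 20, 30]),
                               [1 / 3, 2 / 3, 1.0])
    np.testing.assert_allclose(normalized_ranks([5, 5]), [0.75, 0.75])
    with pytest.raises(ValueError):
        normalized_ranks([])


@settings(derandomize=True, max_examples=40)
@given(st.permutations(list(range(8))))
def test_normalized_ranks_are_permutation_equivariant(perm):
    v = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0, 3.5])
    perm = np.array(perm)
    np.testing.assert_allclose(normalized_ranks(v[perm]),
                               normalized_ranks(v)[perm])


def test_spearman_matches_rank_difference_formula():
    rng = np.random.default_rng(8)
    for _ in range(20):
        x = rng.permutation(rng.normal(size=30))
        y = rng.normal(size=30)
        res = concordance_fitted(y, x)
        assert res.spearman == pytest.approx(spearman_oracle(x, y), abs=1e-12)


def test_concordance_constructed_extremes():
    pure = {"A": np.array([1.0, 2.0, 3.0, 4.0]),
            "B": np.array([4.0, 3.0, 2.0, 1.0])}
    weights = {"A": 0.75, "B": 0.25}
    constructed = 0.75 * pure["A"] + 0.25 * pure["B"]
    perfect = concordance_constructed(pure, constructed, weights)
    assert perfect.spearman == pytest.approx(1.0)
    reversed_ = concordance_constructed(pure, constructed[::-1].copy(), weights)
    assert reversed_.spearman == pytest.approx(-1.0)


def test_concordance_on_noiseless_tpm_is_exact(small_truth, small_counts,
                                               small_lengths):
    tpm = counts_to_tpm(small_counts, small_lengths)
    agg = fit_all(tpm, small_truth.design, "C")
    pure = {t: replicate_mean(tpm, t, agg.feature_ids) for t in ("A", "B")}
    mix = replicate_mean(tpm, "C", agg.feature_ids)
    res = concordance_constructed(pure, mix, small_truth.design.weights("C"))
    assert res.spearman == pytest.approx(1.0, abs=1e-12)


def test_all_tie_concordance_is_flagged_not_nan_propagated():
    res = concordance_fitted(np.array([1.0, 2.0, 3.0]), np.full(3, 5.0))
    assert res.degenerate
    assert np.isnan(res.spearman)
    assert np.isfinite(res.rank_pairs).all()


def test_concordance_length_mismatch():
    with pytest.raises(ValueError):
        concordance_fitted(np.ones(3), np.ones(4))


# ---------------------------------------------------------------------------
# ROC-like curve
# ---------------------------------------------------------------------------

def test_roc_like_perfect_fit():
    curve = roc_like(np.zeros(10), thresholds=[0.0, 0.5, 1.0])
    np.testing.assert_array_equal(curve.proportions, [1.0, 1.0, 1.0])
    assert curve.auc_like == 1.0


def test_roc_like_direct_count():
    curve = roc_like([0.1, -0.2, 0.3], thresholds=[0.15])
    assert curve.proportions[0] == pytest.approx(1 / 3)


def test_roc_like_default_grid_reaches_one():
    rng = np.random.default_rng(9)
    curve = roc_like(rng.normal(size=200))
    assert curve.proportions[-1] == 1.0
    assert len(curve.thresholds) == 101
    assert 0.0 <= curve.auc_like <= 1.0


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1,
                max_size=50))
def test_roc_like_proportions_are_nondecreasing(residuals):
    curve = roc_like(residuals, n_thresholds=21)
    assert (np.diff(curve.proportions) >= 0).all()


def test_roc_like_is_empirical_cdf():
    a = np.array([0.5, 1.5, 2.5, 3.5])
    grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    curve = roc_like(a, thresholds=grid)
    np.testing.assert_allclose(curve.proportions, [0, 0.25, 0.5, 0.75, 1.0])


def test_pooled_grid_is_shared_and_sorted():
    grid = pooled_threshold_grid([[0.1, 0.2], [5.0, -3.0]], n_thresholds=11)
    assert len(grid) == 11
    assert (np.diff(grid) >= 0).all()
    assert grid[-1] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# distribution profiling
# ---------------------------------------------------------------------------

def test_bimodal_generator_shows_two_modes():
    """Pure samples draw from a two-mode log-normal, so their log-scale
    profiles show exactly two modes. Mixture samples blend the pure
    molecule fractions feature-wise (a feature low in A but high in B lands
    between the modes), so only the pure columns are asserted."""
    truth = generate_truth(GeneratorConfig(n_features=400, bimodal_fraction=0.5,
                                           seed=11))
    prof = distribution_profile(render_counts(truth), transform="log")
    pure_modes = {prof.n_modes[sid] for sid in prof.n_modes
                  if sid.startswith(("A_", "B_"))}
    assert pure_modes == {2}


def test_unimodal_generator_shows_one_mode():
    truth = generate_truth(GeneratorConfig(n_features=400, bimodal_fraction=0.0,
                                           seed=11))
    prof = distribution_profile(render_counts(truth), transform="log")
    assert set(prof.n_modes.values()) == {1}


def test_constant_column_flagged_degenerate():
    m = make_matrix({"A_1": np.full(20, 3.0),
                     "B_1": np.arange(20.0)})
    prof = distribution_profile(m)
    assert prof.degenerate["A_1"] and not prof.degenerate["B_1"]
    assert prof.n_modes["A_1"] == 1


def test_profile_bin_edges_shared_across_samples(small_counts):
    prof = distribution_profile(small_counts, transform="log")
    assert prof.densities.shape[1] == len(small_counts.sample_ids)
    # one shared index of bin centres serves every sample column
    assert prof.bin_edges.shape == (61,)


# ---------------------------------------------------------------------------
# cross-unit summary
# ---------------------------------------------------------------------------

def _entries_for(truth, matrices, mixture="C"):
    res = evaluate_units(matrices, truth.design, mixture)
    return res["summaries"]


def test_tpm_ranks_above_depth_confounded_counts(hetero_truth, hetero_counts):
    lengths = pd.Series(hetero_truth.feature_lengths.astype(float),
                        index=hetero_truth.feature_ids)
    summaries = _entries_for(hetero_truth, {
        "count": hetero_counts,
        "tpm": counts_to_tpm(hetero_counts, lengths),
    })
    assert summaries[0].label == "tpm"
    assert summaries[0].max_abs_bias < summaries[1].max_abs_bias


def test_log_distortion_relative_to_tpm(hetero_truth, hetero_counts):
    """On noiseless data the log unit has a strictly larger |intercept| and a
    strictly lower ROC-like area than TPM (the log-induced underestimation)."""
    lengths = pd.Series(hetero_truth.feature_lengths.astype(float),
                        index=hetero_truth.feature_ids)
    summaries = _entries_for(hetero_truth, {
        "tpm": counts_to_tpm(hetero_counts, lengths),
        "log": log_transform(hetero_counts),
    })
    by = {s.label: s for s in summaries}
    assert by["tpm"].intercept_abs < by["log"].intercept_abs
    assert by["tpm"].auc_like > by["log"].auc_like


def test_identical_inputs_give_identical_summary_rows(small_truth, small_counts):
    s = _entries_for(small_truth, {"count": small_counts,
                                   "again": small_counts})
    a, b = s[0], s[1]
    assert a.bias == b.bias
    assert a.intercept_abs == b.intercept_abs
    assert a.auc_like == b.auc_like
    assert a.spearman_fitted == b.spearman_fitted


def test_inconsistent_designs_rejected(small_truth, small_counts):
    res = evaluate_units({"count": small_counts}, small_truth.design, "C")
    other = evaluate_units({"count": small_counts}, small_truth.design, "D")
    entry_c = ("c", res["per_unit"]["count"]["aggregate"],
               res["per_unit"]["count"]["concordance_constructed"],
               res["per_unit"]["count"]["concordance_fitted"],
               res["per_unit"]["count"]["roc"],
               res["per_unit"]["count"]["rescaled"])
    entry_d = ("d", other["per_unit"]["count"]["aggregate"],
               other["per_unit"]["count"]["concordance_constructed"],
               other["per_unit"]["count"]["concordance_fitted"],
               other["per_unit"]["count"]["roc"],
               other["per_unit"]["count"]["rescaled"])
    with pytest.raises(ValueError):
        summarize_methods([entry_c, entry_d])


def test_summary_table_is_flat_and_ranked(small_truth, small_counts):
    table = summary_table(_entries_for(small_truth, {"count": small_counts}))
    assert list(table["rank"]) == [1]
    assert {"unit", "max_abs_bias", "intercept_abs", "auc_like"} <= set(table.columns)
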