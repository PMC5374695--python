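"""Model-assessment analyses for the mixture regression.

Three complementary views of linearity, plus distribution profiling and a
cross-unit ranking table:

* **Rank concordance** — normalized-rank agreement (Spearman) between the
  measured mixture abundance and either the constructed value
  (weights x pure-sample means) or the model's averaged fitted value.
* **ROC-like residual curve** — the proportion of features whose absolute
  residual falls below a threshold, traced over a threshold grid; thresholds
  default to evenly spaced quantiles of the pooled absolute residuals so
  curves from different units share an axis.
* **Rescaled-residual summary** — RMS of the averaged residuals from the
  standardized (rescaled) regression, comparable across units.
* **Distribution profiling** — shared-bin histograms per sample with a simple
  mode count to describe uni/bimodality of the abundance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import DataError
from .linearity import AggregateFit
from .matrix import QuantMatrix


# ---------------------------------------------------------------------------
# rank concordance
# ---------------------------------------------------------------------------

def normalized_ranks(v) -> np.ndarray:
    """Ascending average ranks divided by the vector length; values in (0, 1]."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("normalized_ranks requires a non-empty 1-d vector")
    return stats.rankdata(v, method="average") / v.size


@dataclass
class ConcordanceResult:
    """Normalized rank pairs (reference, comparison) and their Spearman rho.

    ``degenerate`` flags all-tie inputs, for which rank correlation is
    undefined; ``spearman`` is NaN in that case rather than silently wrong.
    """

    rank_pairs: np.ndarray
    spearman: float
    n_features: int
    degenerate: bool = False


def _concordance(reference, comparison) -> ConcordanceResult:
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparison, dtype=float)
    if ref.shape != comp.shape:
        raise ValueError(f"length mismatch: {ref.shape[0]} vs {comp.shape[0]}")
    r_ref = normalized_ranks(ref)
    r_comp = normalized_ranks(comp)
    degenerate = bool(np.ptp(ref) == 0 or np.ptp(comp) == 0)
    rho = float("nan") if degenerate else float(stats.spearmanr(ref, comp).statistic)
    return ConcordanceResult(rank_pairs=np.column_stack([r_ref, r_comp]),
                             spearman=rho, n_features=ref.size,
                             degenerate=degenerate)


def concordance_constructed(pure_means: Mapping[str, Sequence[float]],
                            mixture_mean, weights: Mapping[str, float]
                            ) -> ConcordanceResult:
    """Concordance of the measured mixture mean against the constructed value
    sum_t weight_t x pure_mean_t (the design-truth prediction)."""
    mixture_mean = np.asarray(mixture_mean, dtype=float)
    constructed = np.zeros_like(mixture_mean)
    for t, w in weights.items():
        constructed += w * np.asarray(pure_means[t], dtype=float)
    return _concordance(constructed, mixture_mean)


def concordance_fitted(mixture_mean, mean_fitted) -> ConcordanceResult:
    """Concordance of the measured mixture mean against the regression's
    combination-averaged fitted value."""
    return _concordance(mean_fitted, mixture_mean)


# ---------------------------------------------------------------------------
# ROC-like residual curve
# ---------------------------------------------------------------------------

@dataclass
class RocLikeCurve:
    """Proportion of features with |residual| <= threshold over a grid.

    ``auc_like`` is the mean proportion over the grid — 1 for a perfect fit,
    smaller when large residuals are common. It summarizes the curve for
    ranking; it is a convenience scalar, not a classical AUC.
    """

    thresholds: np.ndarray
    proportions: np.ndarray
    auc_like: float


def pooled_threshold_grid(residual_sets: Sequence[Sequence[float]],
                          n_thresholds: int = 101) -> np.ndarray:
    """Evenly spaced quantiles (0..1) of pooled |residuals| across units, so
    ROC-like curves of different units are evaluated on one shared axis."""
    pooled = np.abs(np.concatenate([np.asarray(r, float).ravel()
                                    for r in residual_sets]))
    if pooled.size == 0:
        raise ValueError("no residuals to pool")
    return np.quantile(pooled, np.linspace(0.0, 1.0, n_thresholds))


def roc_like(residuals, thresholds=None, n_thresholds: int = 101) -> RocLikeCurve:
    """Empirical CDF of absolute residuals on a threshold grid.

    Default thresholds are ``n_thresholds`` evenly spaced quantiles of this
    residual set's own |values|; pass a grid from
    :func:`pooled_threshold_grid` to compare several units.
    """
    a = np.abs(np.asarray(residuals, dtype=float))
    if a.size == 0:
        raise ValueError("roc_like requires at least one residual")
    if not np.isfinite(a).all():
        raise ValueError("residuals must be finite")
    if thresholds is None:
        thresholds = np.quantile(a, np.linspace(0.0, 1.0, n_thresholds))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if (thresholds < 0).any():
        raise ValueError("thresholds must be non-negative")
    proportions = np.array([(a <= t).mean() for t in thresholds])
    return RocLikeCurve(thresholds=thresholds, proportions=proportions,
                        auc_like=float(proportions.mean()))


# ---------------------------------------------------------------------------
# distribution profiling
# ---------------------------------------------------------------------------

@dataclass
class DistributionProfile:
    """Shared-bin density histograms per sample plus a per-sample mode count."""

    transform: str
    bin_edges: np.ndarray
    densities: pd.DataFrame  # rows = bins (indexed by centre), cols = samples
    n_modes: dict[str, int]
    degenerate: dict[str, bool]


def _count_modes(col: np.ndarray, lo: float, hi: float,
                 prominence_frac: float) -> int:
    # Modes are counted on a Gaussian KDE rather than the raw histogram so
    # sampling noise does not split a peak; zero padding lets boundary peaks
    # count. A mode must rise above prominence_frac of the peak density.
    grid = np.linspace(lo, hi, 256)
    dens = stats.gaussian_kde(col)(grid)
    padded = np.r_[0.0, dens, 0.0]
    floor = prominence_frac * padded.max()
    peaks, _ = signal.find_peaks(padded, height=floor, prominence=floor)
    return int(len(peaks))


def distribution_profile(m: QuantMatrix, transform: str = "identity",
                         bins: int = 60, prominence_frac: float = 0.1
                         ) -> DistributionProfile:
    """Per-sample abundance distributions on a common binning.

    ``transform`` is ``identity`` or ``log`` (log2(x+1), requiring
    non-negative values). A mode is a local density maximum exceeding
    ``prominence_frac`` of the sample's peak density; constant columns are
    flagged degenerate (single collapsed bin) instead of profiled.
    """
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    vals = m.values.to_numpy()
    if transform == "log":
        if (vals < 0).any():
            raise ValueError("log transform requires non-negative values")
        vals = np.log2(vals + 1.0)

    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        hi = lo + 1.0  # all samples constant: one degenerate bin
    edges = np.linspace(lo, hi, bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])

    densities = {}
    n_modes: dict[str, int] = {}
    degenerate: dict[str, bool] = {}
    for j, sid in enumerate(m.sample_ids):
        col = vals[:, j]
        degenerate[sid] = bool(np.ptp(col) == 0)
        dens, _ = np.histogram(col, bins=edges, density=True)
        densities[sid] = dens
        n_modes[sid] = (1 if degenerate[sid]
                        else _count_modes(col, lo, hi, prominence_frac))
    return DistributionProfile(
        transform=transform,
        bin_edges=edges,
        densities=pd.DataFrame(densities, index=pd.Index(centres, name="bin_centre")),
        n_modes=n_modes,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# cross-unit summary table
# ---------------------------------------------------------------------------

@dataclass
class MethodSummary:
    """One row of the cross-unit comparison table."""

    label: str
    mixture_type: str
    bias: dict[str, float]            # coefficient mean - design weight
    max_abs_bias: float
    intercept_abs: float
    interval_width: dict[str, float]  # 95% percentile interval widths
    intercept_interval_width: float
    spearman_constructed: float
    spearman_fitted: float
    auc_like: float
    rescaled_residual_rms: float
    rank: int = 0


def summarize_methods(entries: Sequence[tuple]) -> list[MethodSummary]:
    """Build and rank the cross-unit summary table.

    Each entry is ``(label, aggregate, concordance_constructed,
    concordance_fitted, roc_like_curve, rescaled_aggregate)``, all computed on
    the same design and mixture type. The ranking key — |coefficient bias|
    ascending, then |intercept| ascending, then auc_like descending — is a
    convenience composite for ordering the table, not a formal score.
    """
    if not entries:
        raise ValueError("summarize_methods needs at least one entry")
    ref: AggregateFit = entries[0][1]
    summaries: list[MethodSummary] = []
    for label, agg, conc_c, conc_f, roc, resc in entries:
        if (agg.mixture_type != ref.mixture_type
                or agg.pure_types != ref.pure_types
                or agg.weights != ref.weights):
            raise ValueError(f"entry {label!r} was fitted on a different design")
        bias = agg.coefficient_bias()
        summaries.append(MethodSummary(
            label=label,
            mixture_type=agg.mixture_type,
            bias=bias,
            max_abs_bias=max(abs(b) for b in bias.values()),
            intercept_abs=abs(agg.intercept_mean),
            interval_width={t: hi - lo for t, (lo, hi) in agg.coef_interval.items()},
            intercept_interval_width=(agg.intercept_interval[1]
                                      - agg.intercept_interval[0]),
            spearman_constructed=conc_c.spearman,
            spearman_fitted=conc_f.spearman,
            auc_like=roc.auc_like,
            rescaled_residual_rms=float(np.sqrt(np.mean(resc.mean_residuals ** 2))),
        ))
    summaries.sort(key=lambda s: (s.max_abs_bias, s.intercept_abs, -s.auc_like))
    for i, s in enumerate(summaries, start=1):
        s.rank = i
    return summaries


def summary_table(summaries: Sequence[MethodSummary]) -> pd.DataFrame:
    """The summary list as a flat DataFrame (one row per unit, ranked)."""
    rows = []
    for s in summaries:
        row = {"rank": s.rank, "unit": s.label, "mixture_type": s.mixture_type}
        row.update({f"bias_{t}": b for t, b in s.bias.items()})
        row.update({
            "max_abs_bias": s.max_abs_bias,
            "intercept_abs": s.intercept_abs,
            "intercept_interval_width": s.intercept_interval_width,
            "spearman_constructed": s.spearman_constructed,
            "spearman_fitted": s.spearman_fitted,
            "auc_like": s.auc_like,
            "rescaled_residual_rms": s.rescaled_residual_rms,
        })
        row.update({f"interval_width_{t}": w for t, w in s.interval_width.items()})
        rows.append(row)
    return pd.DataFrame(rows)
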