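"""The mixture regression at the core of the linearity evaluation.

For a titration design where mixture sample C is composed of pure samples A
and B at known weights (e.g. 0.75/0.25), each replicate combination — one
replicate of each pure type plus one replicate of the mixture — defines one
ordinary least-squares fit across features:

    C ~ m * A + n * B + eps

If the quantification unit preserves linear mixing, the coefficients recover
the design weights and the intercept is zero. With r replicates per type the
design yields r^3 combination models (64 for the 4/4/4 benchmark layout);
coefficients are aggregated as scalars across combinations, fitted values and
residuals are averaged per feature.

A rescaled variant standardizes every variable by its across-feature mean and
standard deviation before fitting, making residuals comparable across units
with very different ranges.

All operations here are deterministic; randomness lives only in the synthetic
generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import MixtureDesign
from .errors import CollinearityError, DataError, DesignError
from .matrix import QuantMatrix

#: condition number above which the predictor matrix is treated as singular
_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# combination enumeration
# ---------------------------------------------------------------------------

def enumerate_combinations(design: MixtureDesign,
                           mixture_type: str) -> list[dict[str, int]]:
    """All replicate combinations for one mixture regression.

    Returns the Cartesian product of 1-based replicate indices over
    (each pure type in design order, then the mixture type), in lexicographic
    order. A 4/4/4 design yields 64 combinations.
    """
    if mixture_type not in design.mixtures:
        raise DesignError(f"unknown mixture type {mixture_type!r}")
    types = list(design.pure_types) + [mixture_type]
    ranges = [range(1, design.replicates[t] + 1) for t in types]
    return [dict(zip(types, choice)) for choice in itertools.product(*ranges)]


# ---------------------------------------------------------------------------
# single-combination fit
# ---------------------------------------------------------------------------

@dataclass
class CombinationFit:
    """One OLS fit of a mixture replicate on one replicate of each pure type."""

    replicate_choice: dict[str, int]
    coefficients: dict[str, float]
    intercept: float
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    coef_stderr: dict[str, float] = field(default_factory=dict)
    intercept_stderr: float = float("nan")


def fit_combination(y, X: Mapping[str, Sequence[float]],
                    with_intercept: bool = True,
                    replicate_choice: Mapping[str, int] | None = None
                    ) -> CombinationFit:
    """Ordinary least squares of the mixture column on the pure columns.

    Observations are features: ``y`` is the mixture replicate's abundance
    vector, ``X`` maps each pure type to its replicate's vector. Raises
    :class:`CollinearityError` when the predictors are numerically singular
    and ``ValueError`` on length mismatch.
    """
    y = np.asarray(y, dtype=float)
    names = list(X)
    cols = [np.asarray(X[t], dtype=float) for t in names]
    for t, c in zip(names, cols):
        if c.shape != y.shape:
            raise ValueError(f"length mismatch: y has {y.shape[0]} features, "
                             f"{t!r} has {c.shape[0]}")
    n_params = len(names) + (1 if with_intercept else 0)
    if y.size < n_params + 1:
        raise DataError(f"need at least {n_params + 1} features to fit "
                        f"{n_params} parameters, got {y.size}")

    exog = np.column_stack(cols)
    if with_intercept:
        exog = np.column_stack([np.ones(y.size), exog])
    cond = np.linalg.cond(exog)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise CollinearityError(
            f"predictors {names} are collinear (condition number {cond:.3g})")

    res = sm.OLS(y, exog).fit()
    params = res.params
    bse = res.bse
    off = 1 if with_intercept else 0
    return CombinationFit(
        replicate_choice=dict(replicate_choice or {}),
        coefficients={t: float(params[off + i]) for i, t in enumerate(names)},
        intercept=float(params[0]) if with_intercept else 0.0,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=y - np.asarray(res.fittedvalues, dtype=float),
        r_squared=float(res.rsquared),
        coef_stderr={t: float(bse[off + i]) for i, t in enumerate(names)},
        intercept_stderr=float(bse[0]) if with_intercept else float("nan"),
    )


def standardize(v) -> np.ndarray:
    """(v - mean) / sd across features; raises on zero variance."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (v - v.mean()) / sd


def fit_rescaled(y, X: Mapping[str, Sequence[float]],
                 replicate_choice: Mapping[str, int] | None = None
                 ) -> CombinationFit:
    """The mixture regression on standardized variables.

    Each of y and the pure columns is centred by its across-feature mean and
    scaled by its standard deviation before the OLS fit, so residual-vs-fitted
    values are comparable across quantification units with different ranges.
    """
    ys = standardize(y)
    Xs = {t: standardize(v) for t, v in X.items()}
    return fit_combination(ys, Xs, with_intercept=True,
                           replicate_choice=replicate_choice)


# ---------------------------------------------------------------------------
# aggregation over all combinations
# ---------------------------------------------------------------------------

@dataclass
class AggregateFit:
    """Coefficients, fitted values, and residuals aggregated over all
    replicate combinations of one mixture regression.

    Coefficient summaries are across-combination means with empirical
    2.5/97.5 percentile intervals; ``mean_fitted``/``mean_residuals`` are
    per-feature averages over combinations, in the order of ``feature_ids``
    (the features retained by the fit filter).
    """

    mixture_type: str
    pure_types: tuple[str, ...]
    weights: dict[str, float]
    feature_ids: list[str]
    fits: list[CombinationFit]
    rescaled: bool
    unit: str

    def __post_init__(self) -> None:
        coefs = {t: np.array([f.coefficients[t] for f in self.fits])
                 for t in self.pure_types}
        intercepts = np.array([f.intercept for f in self.fits])
        self.coef_values: dict[str, np.ndarray] = coefs
        self.intercept_values: np.ndarray = intercepts
        self.coef_mean = {t: float(v.mean()) for t, v in coefs.items()}
        self.coef_interval = {t: tuple(np.percentile(v, [2.5, 97.5]))
                              for t, v in coefs.items()}
        self.intercept_mean = float(intercepts.mean())
        self.intercept_interval = tuple(np.percentile(intercepts, [2.5, 97.5]))
        self.mean_fitted = np.mean([f.fitted for f in self.fits], axis=0)
        self.mean_residuals = np.mean([f.residuals for f in self.fits], axis=0)
        self.r_squared_mean = float(np.mean([f.r_squared for f in self.fits]))

    @property
    def n_combinations(self) -> int:
        return len(self.fits)

    def combination_table(self) -> pd.DataFrame:
        """One row per combination: replicate choice, coefficients, intercept, R^2."""
        rows = []
        for f in self.fits:
            row = {f"rep_{t}": r for t, r in f.replicate_choice.items()}
            row.update({f"coef_{t}": f.coefficients[t] for t in self.pure_types})
            row["intercept"] = f.intercept
            row["r_squared"] = f.r_squared
            rows.append(row)
        return pd.DataFrame(rows)

    def coefficient_bias(self) -> dict[str, float]:
        """Mean estimate minus the design weight, per pure type."""
        return {t: self.coef_mean[t] - self.weights[t] for t in self.pure_types}

    def to_dict(self) -> dict:
        return {
            "mixture_type": self.mixture_type,
            "unit": self.unit,
            "rescaled": self.rescaled,
            "weights": self.weights,
            "n_combinations": self.n_combinations,
            "n_features": len(self.feature_ids),
            "coef_mean": self.coef_mean,
            "coef_interval": {t: list(v) for t, v in self.coef_interval.items()},
            "intercept_mean": self.intercept_mean,
            "intercept_interval": list(self.intercept_interval),
            "r_squared_mean": self.r_squared_mean,
        }


def _feature_filter(matrix: QuantMatrix, involved: Sequence[str],
                    filter_rule) -> pd.Index:
    sub = pd.concat([matrix.columns_of_type(t) for t in involved], axis=1)
    if filter_rule in (None, "none"):
        keep = pd.Series(True, index=sub.index)
    elif filter_rule == "drop_all_zero":
        keep = (sub != 0).any(axis=1)
    elif callable(filter_rule):
        keep = filter_rule(sub)
    else:
        raise ValueError(f"unknown filter_rule {filter_rule!r}")
    return sub.index[keep]


def fit_all(matrix: QuantMatrix, design: MixtureDesign, mixture_type: str,
            filter_rule="drop_all_zero", rescaled: bool = False
            ) -> AggregateFit:
    """Fit the mixture regression for every replicate combination and aggregate.

    The feature filter (default: drop features that are zero in every sample
    involved in the fit) is applied once, identically for all combinations.
    With ``rescaled=True`` every variable is standardized per combination
    before fitting (the rescaled-model variant).
    """
    if mixture_type not in design.mixtures:
        raise DesignError(f"unknown mixture type {mixture_type!r}")
    for t in design.sample_types:
        have = matrix.replicate_indices(t)
        want = list(range(1, design.replicates[t] + 1))
        if t in (*design.pure_types, mixture_type) and have[:len(want)] != want:
            raise DataError(f"matrix lacks replicates {want} of type {t!r}, has {have}")

    involved = list(design.pure_types) + [mixture_type]
    keep = _feature_filter(matrix, involved, filter_rule)
    n_params = len(design.pure_types) + 1
    if len(keep) < n_params + 1:
        raise DataError(f"only {len(keep)} features remain after filtering; "
                        f"need more than {n_params}")

    fits: list[CombinationFit] = []
    for choice in enumerate_combinations(design, mixture_type):
        y = matrix.column(mixture_type, choice[mixture_type]).loc[keep].to_numpy()
        X = {t: matrix.column(t, choice[t]).loc[keep].to_numpy()
             for t in design.pure_types}
        if rescaled:
            fits.append(fit_rescaled(y, X, replicate_choice=choice))
        else:
            fits.append(fit_combination(y, X, with_intercept=True,
                                        replicate_choice=choice))
    return AggregateFit(
        mixture_type=mixture_type,
        pure_types=design.pure_types,
        weights=design.weights(mixture_type),
        feature_ids=list(keep),
        fits=fits,
        rescaled=rescaled,
        unit=matrix.unit,
    )


def replicate_mean(matrix: QuantMatrix, sample_type: str,
                   feature_ids: Sequence[str] | None = None) -> np.ndarray:
    """Across-replicate mean abundance of a sample type (the 'measured value'
    used by the concordance analyses), optionally restricted to features."""
    cols = matrix.columns_of_type(sample_type)
    if feature_ids is not None:
        cols = cols.loc[list(feature_ids)]
    return cols.mean(axis=1).to_numpy()
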