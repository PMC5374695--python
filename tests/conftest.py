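"""Shared fixtures: small seeded synthetic experiments and hand-built matrices."""

import numpy as np
import pandas as pd
import pytest

from mixlin import (GeneratorConfig, QuantMatrix, generate_truth,
                    infer_sample_info, render_counts)


@pytest.fixture(scope="session")
def small_truth():
    """Noiseless equal-depth titration experiment, 200 features, seed 11."""
    return generate_truth(GeneratorConfig(n_features=200, equal_depth=True,
                                          noise=0.0, seed=11))


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return render_counts(small_truth)


@pytest.fixture(scope="session")
def small_lengths(small_truth):
    return pd.Series(small_truth.feature_lengths.astype(float),
                     index=pd.Index(small_truth.feature_ids, name="feature_id"))


@pytest.fixture(scope="session")
def hetero_truth():
    """Noiseless experiment with heterogeneous library sizes, seed 11."""
    return generate_truth(GeneratorConfig(n_features=200, equal_depth=False,
                                          noise=0.0, seed=11))


@pytest.fixture(scope="session")
def hetero_counts(hetero_truth):
    return render_counts(hetero_truth)


def make_matrix(columns: dict, unit: str = "count",
                feature_ids=None) -> QuantMatrix:
    """Build a QuantMatrix from plain column arrays keyed by TYPE_REP ids."""
    n = len(next(iter(columns.values())))
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(1, n + 1)]
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                          index=pd.Index(feature_ids, name="feature_id"))
    return QuantMatrix(values=values, sample_info=infer_sample_info(values.columns),
                       unit=unit)


def ols_oracle(y, X_columns, with_intercept=True):
    """Independent normal-equations OLS solver (the brute-force oracle).

    Solves (X'X) beta = X'y directly with numpy.linalg.solve; returns
    (intercept, coefficients array).
    """
    y = np.asarray(y, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in X_columns]
    if with_intercept:
        A = np.column_stack([np.ones(y.size)] + cols)
    else:
        A = np.column_stack(cols)
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    if with_intercept:
        return float(beta[0]), beta[1:]
    return 0.0, beta


def spearman_oracle(x, y):
    """Spearman rho via the direct 1 - 6*sum(d^2)/(n(n^2-1)) formula.

    Valid for tie-free vectors only (the classical rank-difference identity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = np.empty(n)
    rx[np.argsort(x)] = np.arange(1, n + 1)
    ry = np.empty(n)
    ry[np.argsort(y)] = np.arange(1, n + 1)
    d = rx - ry
    return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))
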