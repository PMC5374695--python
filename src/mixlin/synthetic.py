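"""Synthetic titration-design expression experiments with known ground truth.

The generator emulates the structure of the SEQC-style benchmark: two pure RNA
sample types (A, B), mixture types composed of them at known proportions
(C = 3:1, D = 1:3 by default), four replicates per type, heterogeneous library
sizes, and right-skewed per-feature expression whose log-scale distribution is
optionally bimodal (a low-expression and a high-expression mode).

Mixing is defined at the molecule-proportion level: each sample type has a
per-feature molecule-fraction vector p (summing to 1), and a mixture's p is
the convex combination of the pure vectors with the declared weights. Fragment
counts are length-weighted, expected count of feature i being

    library_size * p_i * L_i / Z,    Z = mean_t sum_j p_tj * L_j over pure t.

The normalizer Z is shared by every sample of the experiment (a design-level
constant) rather than recomputed per sample: a per-sample normalizer would
make the realized count columns deviate from the exact convex combination of
the pure columns even at equal depth, because the pure samples' length-
weighted totals differ by sampling fluctuation. With the shared Z,
``library_size`` is the expected total fragment count up to a factor
sum_j p_j L_j / Z that is 1 on average and identical in expectation across
samples, and the linear-mixing identities hold exactly: at equal depth a
noiseless mixture count column equals the weighted sum of the pure columns,
and TPM columns are proportional to molecule fractions regardless of depth.
Raw counts remain confounded by per-sample sequencing depth — the mechanism
the downstream linearity evaluation is designed to expose. Replicate noise is
gamma-Poisson (negative binomial) on counts with a single scalar dispersion;
dispersion 0 yields the exact real-valued expected counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import MixtureDesign, WEIGHT_SUM_TOL
from .errors import DesignError
from .matrix import QuantMatrix, SampleInfo, sample_id


@dataclass
class GeneratorConfig:
    """Settings for :func:`generate_truth`.

    Defaults emulate the benchmark's desk-scale shape: 2,000 features, the
    SEQC A/B/C/D design with 4 replicates per type, mean library size 8e6
    fragments with about a quarter of libraries sequenced at double depth,
    and a two-mode log-normal expression profile (low mode log-mean 0, high
    mode log-mean 4, unit log-sd on the natural-log scale).
    """

    n_features: int = 2000
    design: MixtureDesign = field(default_factory=MixtureDesign.seqc)
    mean_library_size: float = 8e6
    double_depth_fraction: float = 0.25
    depth_jitter_sd: float = 0.05
    equal_depth: bool = False
    noise: float = 0.0
    bimodal_fraction: float = 0.5
    low_mode_logmean: float = 0.0
    high_mode_logmean: float = 4.0
    mode_logsd: float = 1.0
    length_logmean: float = math.log(1500.0)
    length_logsd: float = 0.5
    round_counts: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"], MixtureDesign):
            d["design"] = MixtureDesign.from_dict(d["design"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic experiment.

    ``base_expr`` holds the per-feature relative molecule abundance of each
    pure sample type (non-negative, arbitrary scale); ``proportions`` the
    mixture compositions; ``library_sizes`` the expected total fragment count
    per sample (keyed by ``TYPE_REP`` identifiers). With ``noise == 0`` count
    rendering is a deterministic function of these fields.
    """

    n_features: int
    feature_ids: list[str]
    base_expr: dict[str, np.ndarray]
    feature_lengths: np.ndarray
    proportions: dict[str, dict[str, float]]
    n_replicates: dict[str, int]
    library_sizes: dict[str, float]
    noise: float
    bimodal_fraction: float
    seed: int
    round_counts: bool = False

    def __post_init__(self) -> None:
        self.feature_lengths = np.asarray(self.feature_lengths, dtype=float)
        self.base_expr = {t: np.asarray(v, dtype=float) for t, v in self.base_expr.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_features < 2:
            raise ValueError(f"n_features must be >= 2, got {self.n_features}")
        if len(self.feature_ids) != self.n_features:
            raise ValueError("feature_ids length does not match n_features")
        if self.noise < 0:
            raise ValueError("noise (dispersion) must be >= 0")
        if not 0.0 <= self.bimodal_fraction <= 1.0:
            raise ValueError("bimodal_fraction must lie in [0, 1]")
        if not np.isfinite(self.feature_lengths).all() or (self.feature_lengths < 1).any():
            raise ValueError("feature lengths must be finite and >= 1")
        for t, v in self.base_expr.items():
            if v.shape != (self.n_features,):
                raise ValueError(f"base expression of {t!r} has wrong shape")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValueError(f"base expression of {t!r} must be finite and non-negative")
            if v.sum() <= 0:
                raise ValueError(f"base expression of {t!r} sums to zero")
        for mix, weights in self.proportions.items():
            unknown = set(weights) - set(self.base_expr)
            if unknown:
                raise DesignError(f"mixture {mix!r} references unknown pure types {sorted(unknown)}")
            if any(w < 0 for w in weights.values()):
                raise DesignError(f"mixture {mix!r} has negative weights")
            if abs(sum(weights.values()) - 1.0) > WEIGHT_SUM_TOL:
                raise DesignError(f"mixture {mix!r} weights do not sum to 1")
        for sid, ls in self.library_sizes.items():
            if not (math.isfinite(ls) and ls > 0):
                raise ValueError(f"library size of {sid} must be positive, got {ls!r}")

    # -- accessors --------------------------------------------------------
    @property
    def pure_types(self) -> tuple[str, ...]:
        return tuple(self.base_expr)

    @property
    def sample_types(self) -> tuple[str, ...]:
        return self.pure_types + tuple(self.proportions)

    @property
    def design(self) -> MixtureDesign:
        return MixtureDesign(pure_types=self.pure_types,
                             mixtures=self.proportions,
                             replicates=self.n_replicates)

    def sample_ids(self) -> list[str]:
        return [sample_id(t, r)
                for t in self.sample_types
                for r in range(1, self.n_replicates[t] + 1)]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "feature_ids": list(self.feature_ids),
            "base_expr": {t: v.tolist() for t, v in self.base_expr.items()},
            "feature_lengths": self.feature_lengths.tolist(),
            "proportions": self.proportions,
            "n_replicates": self.n_replicates,
            "library_sizes": self.library_sizes,
            "noise": self.noise,
            "bimodal_fraction": self.bimodal_fraction,
            "seed": self.seed,
            "round_counts": self.round_counts,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(**{k: d[k] for k in (
            "n_features", "feature_ids", "base_expr", "feature_lengths",
            "proportions", "n_replicates", "library_sizes", "noise",
            "bimodal_fraction", "seed", "round_counts")})


def generate_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Draw a fully populated :class:`SyntheticTruth` from generator settings.

    Base expression of each pure type is a two-component log-normal mixture
    when ``bimodal_fraction > 0`` (a feature belongs to the low-expression
    mode with that probability), a single log-normal otherwise. Feature
    lengths are log-normal integers (>= 50 bases). Library sizes are the mean
    size, doubled with probability ``double_depth_fraction`` and jittered by a
    log-normal factor, unless ``equal_depth`` is set. Fixed seed implies a
    bit-identical truth.
    """
    if config.n_features < 2:
        raise ValueError(f"n_features must be >= 2, got {config.n_features}")
    design = config.design  # construction already validated proportions
    rng = np.random.default_rng(config.seed)

    base_expr: dict[str, np.ndarray] = {}
    for t in design.pure_types:
        low = rng.random(config.n_features) < config.bimodal_fraction
        logmean = np.where(low, config.low_mode_logmean, config.high_mode_logmean)
        base_expr[t] = rng.lognormal(mean=logmean, sigma=config.mode_logsd)

    lengths = np.maximum(
        50, np.round(rng.lognormal(config.length_logmean, config.length_logsd,
                                   size=config.n_features))
    ).astype(int)

    library_sizes: dict[str, float] = {}
    for t in design.sample_types:
        for r in range(1, design.replicates[t] + 1):
            if config.equal_depth:
                ls = float(config.mean_library_size)
            else:
                doubled = rng.random() < config.double_depth_fraction
                jitter = (rng.lognormal(0.0, config.depth_jitter_sd)
                          if config.depth_jitter_sd > 0 else 1.0)
                ls = float(config.mean_library_size * (2.0 if doubled else 1.0) * jitter)
            library_sizes[sample_id(t, r)] = ls

    feature_ids = [f"F{i:05d}" for i in range(1, config.n_features + 1)]
    return SyntheticTruth(
        n_features=config.n_features,
        feature_ids=feature_ids,
        base_expr=base_expr,
        feature_lengths=lengths,
        proportions={m: design.weights(m) for m in design.mixture_types},
        n_replicates=dict(design.replicates),
        library_sizes=library_sizes,
        noise=float(config.noise),
        bimodal_fraction=float(config.bimodal_fraction),
        seed=int(config.seed),
        round_counts=bool(config.round_counts),
    )


def molecule_proportions(truth: SyntheticTruth, sample_type: str) -> np.ndarray:
    """Per-feature molecule fraction vector of a sample type (sums to 1)."""
    if sample_type in truth.base_expr:
        v = truth.base_expr[sample_type]
        return v / v.sum()
    if sample_type in truth.proportions:
        return truth_mixture_vector(truth, sample_type)
    raise DesignError(f"unknown sample type {sample_type!r}")


def truth_mixture_vector(truth: SyntheticTruth, mixture_type: str) -> np.ndarray:
    """Ground-truth constructed value of a mixture: the convex combination of
    the pure types' molecule fractions with the declared weights."""
    if mixture_type not in truth.proportions:
        raise DesignError(f"unknown mixture type {mixture_type!r}")
    weights = truth.proportions[mixture_type]
    out = np.zeros(truth.n_features)
    for t, w in weights.items():
        v = truth.base_expr[t]
        out += w * (v / v.sum())
    return out


def render_counts(truth: SyntheticTruth) -> QuantMatrix:
    """Render the experiment as a fragment-count matrix.

    Expected count of feature i in a sample is
    ``library_size * p_i * L_i / Z`` with p the sample's molecule fractions,
    L the feature lengths, and Z the design-level normalizer (the mean
    length-weighted total over the pure types; see the module docstring).
    ``noise == 0`` returns the exact expectations (real-valued unless
    ``round_counts``); ``noise > 0`` draws gamma-Poisson counts with that
    dispersion, seeded from the truth.
    """
    lengths = truth.feature_lengths
    z = float(np.mean([(molecule_proportions(truth, t) * lengths).sum()
                       for t in truth.pure_types]))
    cols: dict[str, np.ndarray] = {}
    info: dict[str, SampleInfo] = {}
    for t in truth.sample_types:
        p = molecule_proportions(truth, t)
        fw = p * lengths / z
        for r in range(1, truth.n_replicates[t] + 1):
            sid = sample_id(t, r)
            cols[sid] = truth.library_sizes[sid] * fw
            info[sid] = SampleInfo(sample_type=t, replicate=r,
                                   library_size=truth.library_sizes[sid])

    if truth.noise > 0:
        rng = np.random.default_rng([truth.seed, 1])
        shape = 1.0 / truth.noise
        for sid in cols:  # fixed column order -> reproducible draws
            mu = cols[sid]
            lam = rng.gamma(shape, mu * truth.noise)
            cols[sid] = rng.poisson(lam).astype(float)
    if truth.round_counts:
        cols = {sid: np.round(v) for sid, v in cols.items()}

    values = pd.DataFrame(cols, index=pd.Index(truth.feature_ids, name="feature_id"))
    return QuantMatrix(values=values, sample_info=info, unit="count")


def write_simulation(truth: SyntheticTruth, counts: QuantMatrix, outdir) -> dict[str, Path]:
    """Write the standard simulation artifacts: count matrix TSV, feature
    lengths TSV, truth JSON, and the design YAML. Returns the paths."""
    from .io_units import write_matrix  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "feature_lengths.tsv",
        "truth": outdir / "truth.json",
        "design": outdir / "design.yaml",
    }
    write_matrix(counts, paths["counts"])
    pd.Series(truth.feature_lengths, index=pd.Index(truth.feature_ids, name="feature_id"),
              name="length").to_csv(paths["lengths"], sep="\t")
    paths["truth"].write_text(json.dumps(truth.to_dict(), sort_keys=True))
    truth.design.to_yaml(paths["design"])
    return paths
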