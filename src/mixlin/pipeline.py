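"""End-to-end orchestration: load/convert -> fit -> evaluate -> write artifacts.

The pipeline evaluates each requested quantification unit against each
requested mixture type and writes a fixed artifact layout::

    <out>/
      run.json                       # config echo, config hash, versions
      profiles/<unit>.tsv            # distribution densities (+ modes JSON)
      <mixture>/summary.tsv|json     # ranked cross-unit table
      <mixture>/<unit>/aggregate.json
      <mixture>/<unit>/coefficients.tsv
      <mixture>/<unit>/fitted_residuals.tsv
      <mixture>/<unit>/concordance_constructed.tsv
      <mixture>/<unit>/concordance_fitted.tsv
      <mixture>/<unit>/roc.tsv
      <mixture>/<unit>/rescaled_residuals.tsv

Identical config + inputs produce byte-identical artifacts (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import MixtureDesign
from .errors import DataError, PipelineError
from .evaluation import (concordance_constructed, concordance_fitted,
                         distribution_profile, pooled_threshold_grid, roc_like,
                         summarize_methods, summary_table)
from .io_units import (counts_to_fpkm, counts_to_tpm, log_transform,
                       read_feature_lengths, read_matrix, write_matrix)
from .linearity import fit_all, replicate_mean
from .matrix import QuantMatrix

log = logging.getLogger("mixlin")

SUPPORTED_UNITS = ("count", "tpm", "fpkm", "log")


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run.

    ``units`` are derived from the input count matrix (``log`` means
    log2-transformed counts); TPM/FPKM require a feature-lengths table.
    """

    matrix: Path
    design: Path
    out: Path
    lengths: Path | None = None
    units: tuple[str, ...] = ("count", "tpm", "log")
    mixtures: tuple[str, ...] = ()   # empty = every mixture in the design
    level: str = "gene"
    threshold_grid: int = 101
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.matrix = Path(self.matrix)
        self.design = Path(self.design)
        self.out = Path(self.out)
        self.lengths = Path(self.lengths) if self.lengths else None
        self.units = tuple(u.lower() for u in self.units)
        self.mixtures = tuple(self.mixtures)

    def validate(self) -> None:
        for name in ("matrix", "design"):
            p = getattr(self, name)
            if not p.exists():
                raise PipelineError(f"{name} file does not exist: {p}")
        bad = [u for u in self.units if u not in SUPPORTED_UNITS]
        if bad:
            raise PipelineError(f"unsupported units {bad}; choose from {SUPPORTED_UNITS}")
        needs_len = {"tpm", "fpkm"} & set(self.units)
        if needs_len:
            if self.lengths is None:
                raise PipelineError(f"units {sorted(needs_len)} require a feature-lengths table")
            if not self.lengths.exists():
                raise PipelineError(f"lengths file does not exist: {self.lengths}")
        if self.threshold_grid < 2:
            raise PipelineError("threshold_grid must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        try:
            return cls(**d)
        except TypeError as e:
            raise PipelineError(f"invalid pipeline config {path}: {e}") from e

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("matrix", "design", "out", "lengths"):
            d[k] = str(d[k]) if d[k] is not None else None
        d["units"] = list(self.units)
        d["mixtures"] = list(self.mixtures)
        return d


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _unit_matrices(counts: QuantMatrix, units: Sequence[str],
                   lengths) -> dict[str, QuantMatrix]:
    out: dict[str, QuantMatrix] = {}
    for u in units:
        if u == "count":
            out[u] = counts
        elif u == "tpm":
            out[u] = counts_to_tpm(counts, lengths)
        elif u == "fpkm":
            out[u] = counts_to_fpkm(counts, lengths)
        elif u == "log":
            out[u] = log_transform(counts)
    return out


def evaluate_units(matrices: Mapping[str, QuantMatrix], design: MixtureDesign,
                   mixture_type: str, threshold_grid: int = 101) -> dict:
    """Run the full assessment of several unit matrices on one mixture type.

    Returns a dict with per-unit results (aggregate fits, concordances,
    ROC-like curves, rescaled fits) and the ranked summary list.
    """
    per_unit: dict[str, dict] = {}
    for unit, m in matrices.items():
        agg = fit_all(m, design, mixture_type)
        resc = fit_all(m, design, mixture_type, rescaled=True)
        pure_means = {t: replicate_mean(m, t, agg.feature_ids)
                      for t in design.pure_types}
        mix_mean = replicate_mean(m, mixture_type, agg.feature_ids)
        per_unit[unit] = {
            "aggregate": agg,
            "rescaled": resc,
            "pure_means": pure_means,
            "mixture_mean": mix_mean,
            "concordance_constructed": concordance_constructed(
                pure_means, mix_mean, design.weights(mixture_type)),
            "concordance_fitted": concordance_fitted(mix_mean, agg.mean_fitted),
        }
    grid = pooled_threshold_grid(
        [r["aggregate"].mean_residuals for r in per_unit.values()],
        n_thresholds=threshold_grid)
    for unit, r in per_unit.items():
        r["roc"] = roc_like(r["aggregate"].mean_residuals, thresholds=grid)
    summaries = summarize_methods([
        (unit, r["aggregate"], r["concordance_constructed"],
         r["concordance_fitted"], r["roc"], r["rescaled"])
        for unit, r in per_unit.items()])
    return {"per_unit": per_unit, "summaries": summaries}


def _write_unit_artifacts(outdir: Path, r: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    agg = r["aggregate"]
    _dump_json(agg.to_dict(), outdir / "aggregate.json")
    agg.combination_table().to_csv(outdir / "coefficients.tsv", sep="\t",
                                   index=False, float_format="%.10g")
    pd.DataFrame({
        "feature_id": agg.feature_ids,
        "measured_mean": r["mixture_mean"],
        "mean_fitted": agg.mean_fitted,
        "mean_residual": agg.mean_residuals,
    }).to_csv(outdir / "fitted_residuals.tsv", sep="\t", index=False,
              float_format="%.10g")
    for name in ("concordance_constructed", "concordance_fitted"):
        conc = r[name]
        pd.DataFrame({
            "feature_id": agg.feature_ids,
            "rank_reference": conc.rank_pairs[:, 0],
            "rank_comparison": conc.rank_pairs[:, 1],
        }).to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    roc = r["roc"]
    pd.DataFrame({"threshold": roc.thresholds, "proportion": roc.proportions}
                 ).to_csv(outdir / "roc.tsv", sep="\t", index=False,
                          float_format="%.10g")
    resc = r["rescaled"]
    pd.DataFrame({
        "feature_id": resc.feature_ids,
        "mean_fitted": resc.mean_fitted,
        "mean_residual": resc.mean_residuals,
    }).to_csv(outdir / "rescaled_residuals.tsv", sep="\t", index=False,
              float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full evaluation described by ``config``.

    Returns ``{mixture_type: [MethodSummary, ...]}`` and writes the artifact
    tree under ``config.out``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    out = config.out
    out.mkdir(parents=True, exist_ok=True)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    log.info("mixlin %s run, config hash %s, seed %d",
             __version__, cfg_hash[:12], config.seed)

    try:
        counts = read_matrix(config.matrix, "generic_tsv", unit="count",
                             level=config.level)
    except Exception as e:
        raise PipelineError(f"stage load-matrix failed on {config.matrix}: {e}") from e
    design = MixtureDesign.from_yaml(config.design)
    lengths = (read_feature_lengths(config.lengths)
               if config.lengths is not None else None)
    mixtures = config.mixtures or design.mixture_types
    unknown = [m for m in mixtures if m not in design.mixture_types]
    if unknown:
        raise PipelineError(f"mixture types {unknown} not declared in the design")

    try:
        matrices = _unit_matrices(counts, config.units, lengths)
    except DataError as e:
        raise PipelineError(f"stage unit-conversion failed: {e}") from e

    profile_dir = out / "profiles"
    profile_dir.mkdir(exist_ok=True)
    modes: dict[str, dict[str, int]] = {}
    for unit, m in matrices.items():
        prof = distribution_profile(m, transform="identity" if unit == "log" else "log")
        prof.densities.to_csv(profile_dir / f"{unit}.tsv", sep="\t",
                              float_format="%.10g")
        modes[unit] = prof.n_modes
    _dump_json(modes, profile_dir / "modes.json")

    results: dict[str, list] = {}
    for mix in mixtures:
        log.info("evaluating mixture %s over units %s", mix, list(config.units))
        try:
            res = evaluate_units(matrices, design, mix,
                                 threshold_grid=config.threshold_grid)
        except Exception as e:
            raise PipelineError(f"stage evaluate[{mix}] failed: {e}") from e
        mixdir = out / mix
        for unit, r in res["per_unit"].items():
            _write_unit_artifacts(mixdir / unit, r)
        table = summary_table(res["summaries"])
        table.to_csv(mixdir / "summary.tsv", sep="\t", index=False,
                     float_format="%.10g")
        _dump_json(json.loads(table.to_json(orient="records")),
                   mixdir / "summary.json")
        results[mix] = res["summaries"]

    _dump_json({"config": cfg_dict, "config_hash": cfg_hash,
                "mixlin_version": __version__,
                "numpy_version": np.__version__,
                "seed": config.seed},
               out / "run.json")
    return results
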