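"""Render a human-readable report from a pipeline results directory.

The report is Markdown built from the TSV/JSON artifacts that
:func:`mixlin.pipeline.run_pipeline` writes; with ``plots=True`` it also
saves PNG figures (coefficient jitter, rank-rank scatter, ROC-like curves,
rescaled residual-vs-fitted) next to the report. All plot data stays
available as TSV for external plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import PipelineError


def _markdown_table(df: pd.DataFrame, floatfmt: str = ".4g") -> str:
    def cell(v):
        if isinstance(v, float):
            return format(v, floatfmt)
        return str(v)

    header = list(map(str, df.columns))
    rows = [[cell(v) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(header), sep] + [line(r) for r in rows])


def _find_mixtures(results: Path) -> list[str]:
    return sorted(p.name for p in results.iterdir()
                  if p.is_dir() and (p / "summary.tsv").exists())


def _units_in(mixdir: Path) -> list[str]:
    return sorted(p.name for p in mixdir.iterdir()
                  if p.is_dir() and (p / "aggregate.json").exists())


def render_report(results_dir, out_path, plots: bool = False) -> Path:
    """Write the Markdown report; returns the report path."""
    results = Path(results_dir)
    out_path = Path(out_path)
    if not results.is_dir():
        raise PipelineError(f"results directory does not exist: {results}")
    mixtures = _find_mixtures(results)
    if not mixtures:
        raise PipelineError(f"no evaluation results found under {results}")

    lines: list[str] = ["# Mixture-linearity evaluation report", ""]
    run_file = results / "run.json"
    if run_file.exists():
        run = json.loads(run_file.read_text())
        lines += [f"Pipeline version {run.get('mixlin_version', '?')}, "
                  f"config hash `{run.get('config_hash', '?')[:12]}`, "
                  f"seed {run.get('seed', '?')}.", ""]

    modes_file = results / "profiles" / "modes.json"
    if modes_file.exists():
        modes = json.loads(modes_file.read_text())
        lines += ["## Distribution profiles", "",
                  "Detected modes per sample (log-scale histograms for "
                  "linear units):", ""]
        for unit, per_sample in sorted(modes.items()):
            counts = sorted(set(per_sample.values()))
            lines.append(f"- **{unit}**: modes per sample {counts} "
                         f"(densities in `profiles/{unit}.tsv`)")
        lines.append("")

    for mix in mixtures:
        mixdir = results / mix
        table = pd.read_csv(mixdir / "summary.tsv", sep="\t")
        lines += [f"## Mixture {mix}", "",
                  "Units ranked by |coefficient bias|, then |intercept|, "
                  "then ROC-like area:", "",
                  _markdown_table(table), ""]
        for unit in _units_in(mixdir):
            agg = json.loads((mixdir / unit / "aggregate.json").read_text())
            coef = ", ".join(f"{t}: {v:.4g}" for t, v in
                             sorted(agg["coef_mean"].items()))
            lines.append(
                f"- **{unit}** ({agg['n_combinations']} combination models, "
                f"{agg['n_features']} features): coefficients {coef}; "
                f"intercept {agg['intercept_mean']:.4g}; "
                f"mean R^2 {agg['r_squared_mean']:.6g}")
        lines.append("")

    if plots:
        figures = _render_figures(results, mixtures, out_path.parent)
        if figures:
            lines += ["## Figures", ""]
            lines += [f"![{f.stem}]({f.name})" for f in figures]
            lines.append("")

    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text("\n".join(lines))
    return out_path


def _render_figures(results: Path, mixtures: list[str], outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    for mix in mixtures:
        mixdir = results / mix
        units = _units_in(mixdir)

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for unit in units:
            coefs = pd.read_csv(mixdir / unit / "coefficients.tsv", sep="\t")
            coef_cols = [c for c in coefs.columns if c.startswith("coef_")]
            for ax, col in zip(axes, coef_cols[:2]):
                ax.plot([unit] * len(coefs), coefs[col], "o", alpha=0.4, ms=3)
                ax.set_title(col)
        for ax in axes:
            ax.tick_params(axis="x", rotation=45)
        fig.suptitle(f"Mixture {mix}: per-combination coefficients")
        fig.tight_layout()
        p = outdir / f"coefficients_{mix}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(5, 4))
        for unit in units:
            roc = pd.read_csv(mixdir / unit / "roc.tsv", sep="\t")
            ax.plot(range(len(roc)), roc["proportion"], label=unit)
        ax.set_xlabel("threshold grid index (pooled |residual| quantiles)")
        ax.set_ylabel("proportion |residual| <= threshold")
        ax.legend()
        ax.set_title(f"Mixture {mix}: ROC-like residual curves")
        fig.tight_layout()
        p = outdir / f"roc_{mix}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
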