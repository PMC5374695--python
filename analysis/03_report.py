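#!/usr/bin/env python
"""Render the Markdown report (with figures) from the evaluation artifacts.

Requires 02_evaluate_linearity.py to have run; writes results/report.md plus
PNG figures of the per-combination coefficients and ROC-like curves.
"""

from pathlib import Path

from mixlin import render_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    path = render_report(ROOT / "evaluation", ROOT / "report.md", plots=True)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
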