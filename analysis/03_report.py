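"""Render the human-readable summary of the analysis bundle:
limitation-call counts per age x N cell, significant ANOVA terms and the
strongest RE-root correlations.

Reads results/analysis/; writes results/report.md and prints it.
"""
from pathlib import Path

from rhizostoich import run_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    text = run_report(ROOT / "results" / "analysis")
    out = ROOT / "results" / "report.md"
    out.write_text(text)
    print(text)
    print(f"(written to {out})")


if __name__ == "__main__":
    main()
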