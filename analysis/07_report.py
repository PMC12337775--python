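"""Figures and summary for the cohort run: dilation versus distance and
recovered velocities with truth deltas.  Reads the outputs of steps 01-02
and writes results/report/."""

from pathlib import Path

from vasodyn.config import RunConfig
from vasodyn.pipeline import run_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = RunConfig(n_trials=10, seed=1)
    out = run_report(cfg, ROOT / "results" / "dataset",
                     ROOT / "results" / "tables", ROOT / "results" / "report")
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
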