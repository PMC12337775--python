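"""Generate the synthetic two-genotype cohort used by the downstream steps.

Writes, per genotype (control: 4.13 mm/s wave, 0.25 s rise, 1600 µm decay;
knockout: 1.53 mm/s, proportionally slower rise, 800 µm decay), a rendered
multi-trial IOS movie of a 2.1 mm pial artery, the vessel network, trial
and behavior tables, and the ground-truth JSON under results/dataset/.
"""

from pathlib import Path

from vasodyn.config import RunConfig
from vasodyn.pipeline import run_simulate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dataset"


def main() -> None:
    cfg = RunConfig(n_trials=10, seed=1)
    run_simulate(cfg, OUT, force=True)
    print(f"wrote synthetic cohort ({cfg.n_trials} trials/genotype, "
          f"seed {cfg.seed}) to {OUT}")


if __name__ == "__main__":
    main()
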