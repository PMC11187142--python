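#!/usr/bin/env python
"""Generate the synthetic NREM study used by all downstream analyses.

Writes a two-minute continuous 8-channel recording (EDF, under scratch/ —
it is a binary artifact) with ground-truth SO/spindle/ripple events, plus
the trial tables of the matched retrieval + TMR task dataset (TSV, under
results/). Everything is seeded; re-running reproduces the files bit for
bit.
"""

from pathlib import Path

from ripplecue import SimParams
from ripplecue.io import write_table
from ripplecue.pipeline import PipelineConfig, make_fixture
from ripplecue.synth import make_task_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    sim = SimParams(fs=500.0, n_channels=8, n_trials=12, seed=SEED,
                    duration=120.0)
    cfg = PipelineConfig(sim=sim, seed=SEED)

    fixture_dir = ROOT / "scratch" / "fixture"
    paths = make_fixture(cfg, fixture_dir)
    print(f"fixture written to {fixture_dir}:")
    for name, p in paths.items():
        print(f"  {name}: {p.name} ({p.stat().st_size} bytes)")

    retrieval, tmr, gt = make_task_dataset(sim)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_table(gt.trials, out / "trial_table.tsv")
    write_table(gt.events, out / "injected_events.tsv")
    n_rip = int((gt.events["type"] == "ripple").sum())
    n_sp = int((gt.events["type"] == "spindle").sum())
    print(f"task dataset: {retrieval.n_trials} retrieval trials, "
          f"{tmr.n_trials} TMR trials; injected {n_sp} spindles and "
          f"{n_rip} coupled ripples (tables in results/)")


if __name__ == "__main__":
    main()
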