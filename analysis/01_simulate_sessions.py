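"""Simulate the three learning-stage sessions.

Generates one Go/No-go session per learning stage (stage 1: 50% correct, no
choice coupling; stage 2: 65%, intermediate coupling; stage 3: 85%, strong
coupling; stimulus tuning identical throughout) and writes the raw session
containers under results/sessions/.  Every downstream script reads from
there, so the whole analysis is reproducible from this single seed.
"""

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from intersectinfo.io import write_session, write_trials
from intersectinfo.synthetic import (SessionConfig, classify_stage,
                                     generate_session, stage_config)

SEED = 2024
OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "sessions"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = SessionConfig(n_neurons=80, n_trials=200, seed=SEED)
    for stage in (1, 2, 3):
        cfg = stage_config(stage, base)
        rng = np.random.default_rng([SEED, stage])
        trials, fluor, truth = generate_session(cfg, rng)
        write_trials(trials, OUT / f"trials_stage{stage}.csv")
        write_session(OUT / f"session_stage{stage}.h5", fluor,
                      spikes=truth.spikes, seed=SEED)
        perf = trials["outcome"].isin(["Hit", "CR"]).mean()
        print(f"stage {stage}: {cfg.n_neurons} neurons, {cfg.n_trials} trials, "
              f"observed performance {perf:.2f} "
              f"(classified stage {classify_stage(perf)}), "
              f"{int(truth.spikes.sum())} ground-truth spikes")
    print(f"sessions written to {OUT}")


if __name__ == "__main__":
    main()
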