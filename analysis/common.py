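"""Shared cohort construction for the numbered analysis drivers.

The four experiment variants are simulated at the study's recruitment sizes
(LAN 24, LAS 12, rLAN 12, sLAN 10 participants; 80 trials each) from the
hybrid generative model with a fixed seed, reduced to dwell metrics once, and
cached as CSV under scratch/cohorts so the later drivers start from tables.
"""

from pathlib import Path

import pandas as pd

import gazeconf as g

ROOT = Path(__file__).resolve().parents[1]
CACHE = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

COHORTS = {"LAN": 24, "LAS": 12, "rLAN": 12, "sLAN": 10}
SEED = 2025


def build_cohorts(force: bool = False) -> dict[str, dict[str, pd.DataFrame]]:
    """Simulate (or load from cache) every variant's kept trials, exclusion
    report, per-interval metrics and attention times."""
    CACHE.mkdir(parents=True, exist_ok=True)
    out = {}
    for i, (exp, n_p) in enumerate(COHORTS.items()):
        paths = {name: CACHE / f"{exp}_{name}.csv"
                 for name in ("trials", "kept", "metrics", "att", "exclusions", "truth")}
        if force or not all(p.exists() for p in paths.values()):
            cfg = g.GenerativeConfig(n_participants=n_p, n_trials=80,
                                     experiment=exp, seed=SEED + i)
            gaze, trials, truth = g.simulate_dataset(cfg)
            kept, exclusions = g.exclude_trials(trials)
            metrics = g.metrics_table(gaze, kept, cfg.geometry)
            att = g.attention_times(metrics, kept)
            for name, df in (("trials", trials), ("kept", kept), ("metrics", metrics),
                             ("att", att), ("exclusions", exclusions), ("truth", truth)):
                df.to_csv(paths[name], index=False)
        out[exp] = {name: pd.read_csv(p) for name, p in paths.items()}
    RESULTS.mkdir(exist_ok=True)
    return out
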