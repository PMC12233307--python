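import gazeconf as g
import pytest


@pytest.fixture(scope="session")
def hybrid_cohort():
    """One simulated hybrid-model cohort with its derived tables, shared by
    the slower integration-style tests."""
    cfg = g.GenerativeConfig(n_participants=8, n_trials=80, seed=42)
    gaze, trials, truth = g.simulate_dataset(cfg)
    kept, report = g.exclude_trials(trials)
    metrics = g.metrics_table(gaze, kept, cfg.geometry)
    att = g.attention_times(metrics, kept)
    return {
        "cfg": cfg, "gaze": gaze, "trials": trials, "truth": truth,
        "kept": kept, "metrics": metrics, "att": att,
    }
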