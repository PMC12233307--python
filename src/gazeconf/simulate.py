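"""Synthetic experiment generator.

Emulates one cohort of the binary context-dependent decision task: two lateral
areas of interest on a 1920x1080 screen, a Stimulus-On interval (4 s, or 2 s in
the short-observation variant), a GO signal, and a 4 s Stimulus-Off response
window. Gaze alternates between the two AOIs with gamma-distributed dwell
durations separated by brief saccade gaps; choices and decision times arise
from a bounded diffusion whose drift may be gated by the attended option;
confidence ratings are produced by one of three linear observation models of
the per-option attention times, plus reporting noise; reward / interest /
complexity ratings are correlated with trial difficulty.

The clock origin of every trial is stimulus onset. Attention-gated dwells run
until the diffusion commits to a bound; after commitment gaze partially
disengages while the images are still visible (each pre-GO dwell is redirected
off-AOI with probability ``post_commit_off_prob`` — the visible stimuli keep
attracting fixations) and fully disengages to the screen centre once the
images are gone, until the button press; alternating fixations resume after
the press (the double-checking phase) until the end of the response window.

Ground truth (latent attention times, true confidence, drifts, generating
coefficients) is written to a separate table so downstream stages can never
read it by accident.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GenerativeConfig, ScreenGeometry, TrialTimeline
from .ddm import DDMParams, predict_confidence, simulate_ddm_parallel, simulate_ddm_sequential

__all__ = [
    "simulate_attention_schedule",
    "generate_gaze_stream",
    "ratings_from_latents",
    "simulate_dataset",
    "selected_side_from_button",
]

Segment = tuple[str, float, float]  # (side, start_ms, end_ms)

GAZE_COLUMNS = ["participant_id", "trial_index", "t_ms", "x_px", "y_px", "valid"]
TRIAL_COLUMNS = [
    "participant_id", "experiment", "trial_index", "go_time_ms", "stim_on_ms",
    "button", "decision_time_ms", "C", "R", "I", "CM",
]
TRUTH_COLUMNS = [
    "participant_id", "trial_index", "dt1_ms", "dt2_ms", "confidence_true",
    "model", "alpha0", "alpha1", "alpha2", "mu", "sigma", "theta", "mu1", "mu2",
]


def simulate_attention_schedule(
    duration_ms: float,
    dwell_mean_ms: float,
    dwell_shape: float = 4.0,
    gap_ms: float = 40.0,
    rng: np.random.Generator | int | None = None,
    first_side: Optional[str] = None,
) -> list[Segment]:
    """Alternating left/right dwell segments covering [0, duration_ms].

    Dwell durations are gamma distributed with the given shape and mean;
    consecutive dwells are separated by a fixed saccade gap and never repeat a
    side. The first side is drawn at random unless given.
    """
    if dwell_mean_ms <= 0 or dwell_shape <= 0:
        raise ValueError("dwell parameters must be positive")
    if gap_ms < 0:
        raise ValueError("gap_ms must be nonnegative")
    rng = np.random.default_rng(rng)
    if first_side is None:
        first_side = "left" if rng.random() < 0.5 else "right"
    elif first_side not in ("left", "right"):
        raise ValueError("first_side must be 'left' or 'right'")

    segments: list[Segment] = []
    t = 0.0
    side = first_side
    scale = dwell_mean_ms / dwell_shape
    while t < duration_ms:
        dur = float(rng.gamma(dwell_shape, scale))
        end = min(t + dur, duration_ms)
        if end > t:
            segments.append((side, t, end))
        t = t + dur + gap_ms
        side = "right" if side == "left" else "left"
    return segments


def generate_gaze_stream(
    schedule: Sequence[Segment],
    geometry: ScreenGeometry,
    jitter_sd_px: float = 25.0,
    rng: np.random.Generator | int | None = None,
    duration_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Sample a gaze stream (t_ms, x_px, y_px, valid) from dwell segments.

    During a left/right dwell the gaze sits at that AOI's centre with isotropic
    Gaussian jitter; during an 'off' segment it sits at the screen centre
    (valid but outside both AOIs); between segments (saccade gaps) samples are
    flagged invalid. Samples are emitted at geometry.sample_rate_hz from t=0.
    """
    rng = np.random.default_rng(rng)
    if duration_ms is None:
        duration_ms = max((e for _, _, e in schedule), default=0.0)
    period = geometry.sample_period_ms
    n = int(math.floor(duration_ms / period + 1e-9))
    t = np.arange(n) * period
    if n == 0 or not schedule:
        return pd.DataFrame({"t_ms": t, "x_px": np.zeros(0), "y_px": np.zeros(0),
                             "valid": np.zeros(0, dtype=int)})

    starts = np.array([s for _, s, _ in schedule])
    ends = np.array([e for _, _, e in schedule])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_c = np.clip(idx, 0, len(schedule) - 1)
    in_seg = (idx >= 0) & (t < ends[idx_c])

    cx, cy = geometry.width_px / 2.0, geometry.height_px / 2.0
    x = np.full(n, cx)
    y = np.full(n, cy)
    valid = np.zeros(n, dtype=int)
    jitter = rng.normal(0.0, jitter_sd_px, size=(n, 2)) if jitter_sd_px > 0 else np.zeros((n, 2))
    sides = np.array([s for s, _, _ in schedule])
    for side in ("left", "right", "off"):
        m = in_seg & (sides[idx_c] == side)
        if not m.any():
            continue
        ax, ay = (cx, cy) if side == "off" else geometry.aoi_center(side)
        x[m] = ax + jitter[m, 0]
        y[m] = ay + jitter[m, 1]
        valid[m] = 1
    return pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "valid": valid})


def ratings_from_latents(
    confidence_true: float,
    difficulty_z: float,
    rng: np.random.Generator | int | None = None,
    noise_sd: float = 0.05,
    scale_max: int = 10,
) -> dict[str, int]:
    """Discrete 0..scale_max ratings from the latent confidence and a
    standardized trial-difficulty latent.

    C = clip(round(scale_max * (confidence_true + noise))); complexity rises
    with difficulty, reward falls with it, interest is weakly related; all are
    clipped to the reporting scale.
    """
    if not 0.0 <= confidence_true <= 1.0:
        raise ValueError("confidence_true must lie in [0, 1]")
    rng = np.random.default_rng(rng)

    def _scale(v: float) -> int:
        return int(np.clip(round(scale_max * v), 0, scale_max))

    c = _scale(confidence_true + rng.normal(0.0, noise_sd))
    cm = _scale(0.5 + 0.15 * difficulty_z + rng.normal(0.0, 0.15))
    r = _scale(0.5 - 0.08 * difficulty_z + rng.normal(0.0, 0.20))
    i = _scale(0.5 + 0.05 * difficulty_z + rng.normal(0.0, 0.20))
    return {"C": c, "R": r, "I": i, "CM": cm}


def selected_side_from_button(button: str, experiment: str) -> str:
    """Image side implied by a button press (the motor-reversal variant swaps
    button and image side)."""
    if button not in ("left", "right", "none"):
        raise ValueError(f"unknown button {button!r}")
    if button == "none":
        return "none"
    if experiment == "rLAN":
        return "right" if button == "left" else "left"
    return button


def _clip_segments(schedule: Sequence[Segment], t_end: float) -> list[Segment]:
    out = []
    for side, s, e in schedule:
        if s >= t_end:
            break
        out.append((side, s, min(e, t_end)))
    return out


def _aoi_time(segments: Sequence[Segment], side: str, t_end: float) -> float:
    return sum(min(e, t_end) - s for sd, s, e in segments if sd == side and s < t_end)


# standardization constants of the difficulty latent -|mu1 - mu2| under the
# default truncated-normal value draw (simulation-derived, fixed)
_DIFF_MEAN = 0.11
_DIFF_SD = 0.08


def _simulate_trial(cfg: GenerativeConfig, timeline: TrialTimeline,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, dict, dict]:
    span = timeline.decision_span_ms
    go = timeline.go_time_ms

    mu1 = max(0.0, rng.normal(cfg.value_mean, cfg.value_sd))
    mu2 = max(0.0, rng.normal(cfg.value_mean, cfg.value_sd))
    params = DDMParams(mu1=mu1, mu2=mu2, sigma=cfg.ddm.sigma,
                       theta=cfg.ddm.theta, dt_ms=cfg.ddm.dt_ms)

    schedule = simulate_attention_schedule(
        span, cfg.dwell_mean_ms, cfg.dwell_shape, cfg.saccade_gap_ms, rng)

    if cfg.model == "parallel":
        trace = simulate_ddm_parallel(params, rng, max_time_s=span / 1000.0)
    else:  # sequential dynamics drive both the sequential and hybrid cohorts
        trace = simulate_ddm_sequential(params, schedule, rng, max_time_s=span / 1000.0)

    t_c = None if trace.decision_time_s is None else trace.decision_time_s * 1000.0
    latency = max(50.0, rng.normal(cfg.motor_latency_mean_ms, cfg.motor_latency_sd_ms))

    if t_c is None:
        button = "none"
        press = None
        executed = list(schedule)
    else:
        press = max(t_c, go) + latency
        if press > go + timeline.response_window_ms:
            button = "none"
            press = None
        else:
            choice_side = "left" if trace.choice == "option1" else "right"
            button = choice_side if cfg.experiment != "rLAN" else (
                "right" if choice_side == "left" else "left")
        # pre-commitment dwells are kept; the dwell straddling the commitment
        # finishes (attentional inertia), later pre-GO dwells are redirected
        # off-AOI with post_commit_off_prob while the images remain visible
        executed = []
        last_side = "left"
        commit_end = t_c
        for sd, s, e in schedule:
            if s < t_c:
                executed.append((sd, s, e))
                last_side = sd
                commit_end = max(commit_end, e)
            elif s < go:
                redirected = rng.random() < cfg.post_commit_off_prob
                executed.append(("off" if redirected else sd, s, min(e, go)))
                if not redirected:
                    last_side = sd
                commit_end = max(commit_end, min(e, go))
            else:
                break
        resume_at = press if press is not None else span
        executed = [(sd, s, min(e, resume_at)) for sd, s, e in executed if s < resume_at]
        commit_end = min(commit_end, resume_at)
        if commit_end < resume_at:
            executed.append(("off", commit_end, resume_at))
        if press is not None and press < span:
            first = "right" if last_side == "left" else "left"
            tail = simulate_attention_schedule(
                span - press, cfg.dwell_mean_ms, cfg.dwell_shape,
                cfg.saccade_gap_ms, rng, first_side=first)
            executed.extend((sd, s + press, e + press) for sd, s, e in tail)

    ud_end = press if press is not None else go + timeline.response_window_ms
    if button == "none":
        selected = "none"
        t_left = _aoi_time(executed, "left", ud_end)
        t_right = _aoi_time(executed, "right", ud_end)
        sel_side = "left" if t_left >= t_right else "right"
    else:
        sel_side = "left" if trace.choice == "option1" else "right"
        selected = sel_side
    dt1_ms = _aoi_time(executed, sel_side, ud_end)
    dt2_ms = _aoi_time(executed, "right" if sel_side == "left" else "left", ud_end)

    conf_lin = predict_confidence(cfg.alpha, dt1_ms / 1000.0, dt2_ms / 1000.0) \
        if (dt1_ms + dt2_ms) > 0 else cfg.alpha.alpha0
    conf_true = float(np.clip(conf_lin, 0.0, 1.0))
    difficulty_z = (_DIFF_MEAN - abs(mu1 - mu2)) / _DIFF_SD
    ratings = ratings_from_latents(conf_true, difficulty_z, rng,
                                   cfg.rating_noise_sd, cfg.rating_scale_max)

    gaze = generate_gaze_stream(executed, cfg.geometry, cfg.jitter_sd_px, rng,
                                duration_ms=span)
    trial = {
        "experiment": cfg.experiment,
        "go_time_ms": go,
        "stim_on_ms": timeline.stim_on_ms,
        "button": button,
        "decision_time_ms": (press - go) if press is not None else np.nan,
        **ratings,
    }
    truth = {
        "dt1_ms": dt1_ms, "dt2_ms": dt2_ms, "confidence_true": conf_true,
        "model": cfg.model, "alpha0": cfg.alpha.alpha0, "alpha1": cfg.alpha.alpha1,
        "alpha2": cfg.alpha.alpha2 if cfg.alpha.alpha2 is not None else np.nan,
        "mu": mu1 - mu2, "sigma": params.sigma, "theta": params.theta,
        "mu1": mu1, "mu2": mu2, "selected_side": selected,
    }
    return gaze, trial, truth


def simulate_dataset(cfg: GenerativeConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: (gaze table, trial table, ground-truth table).

    Fully reproducible from cfg.seed: per-participant and per-trial random
    streams are spawned from one seed sequence.
    """
    timeline = cfg.timeline
    gaze_parts: list[pd.DataFrame] = []
    trial_rows: list[dict] = []
    truth_rows: list[dict] = []
    root = np.random.SeedSequence(cfg.seed)
    for pid, pseq in enumerate(root.spawn(cfg.n_participants)):
        for trial_idx, tseq in enumerate(pseq.spawn(cfg.n_trials)):
            rng = np.random.default_rng(tseq)
            gaze, trial, truth = _simulate_trial(cfg, timeline, rng)
            gaze.insert(0, "trial_index", trial_idx)
            gaze.insert(0, "participant_id", pid)
            gaze_parts.append(gaze)
            trial_rows.append({"participant_id": pid, "trial_index": trial_idx, **trial})
            truth_rows.append({"participant_id": pid, "trial_index": trial_idx, **truth})
    gaze_df = pd.concat(gaze_parts, ignore_index=True)[GAZE_COLUMNS]
    trials_df = pd.DataFrame(trial_rows)[TRIAL_COLUMNS]
    truth_df = pd.DataFrame(truth_rows)[TRUTH_COLUMNS + ["selected_side"]]
    return gaze_df, trials_df, truth_df
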