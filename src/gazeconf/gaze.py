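"""Reduction of gaze streams to per-trial, per-interval oculomotor metrics.

A *dwell* is a maximal run of valid samples inside one AOI, allowing internal
gaps up to ``max_gap_ms`` (blinks, single stray samples) and discarding runs
shorter than ``min_dwell_ms``. Per interval (Stimulus-On, Stimulus-Off until
the decision, Stimulus-Off past the decision) the metrics are the left/right
dwell times, the fraction of the interval spent on the selected option's AOI,
the number of changes of target (#CoT: adjacent dwells on different sides)
and its rate (fCoT, Hz), and the log right/left time ratio used by the
psychometric fit. All intervals are half-open [start, end) in trial-relative
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScreenGeometry

__all__ = [
    "DwellRecord",
    "Interval",
    "extract_dwells",
    "compute_trial_metrics",
    "log_time_ratio",
    "exclude_trials",
    "intervals_for_trial",
    "metrics_table",
]

METRICS_COLUMNS = [
    "participant_id", "trial_index", "interval", "t_left_ms", "t_right_ms",
    "t_selected_frac", "n_cot", "f_cot", "log_ratio",
]


@dataclass(frozen=True)
class DwellRecord:
    side: str          # 'left' | 'right'
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"invalid dwell side {self.side!r}")
        if self.end_ms <= self.start_ms:
            raise ValueError("dwell must have positive duration")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class Interval:
    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms < self.start_ms:
            raise ValueError(f"interval {self.name}: end before start")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def extract_dwells(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    min_dwell_ms: float = 100.0,
    max_gap_ms: float = 80.0,
    trial_label: str = "",
) -> list[DwellRecord]:
    """Segment a gaze stream into per-AOI dwells.

    Consecutive in-AOI samples on the same side merge into one dwell when the
    time between them does not exceed ``max_gap_ms``; dwells shorter than
    ``min_dwell_ms`` are discarded. Invalid and off-AOI samples belong to no
    dwell. A dwell's end is the time of its last sample plus one sample
    period (half-open convention).
    """
    t = np.asarray(samples["t_ms"], dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError(f"gaze samples are not time-ordered{' in trial ' + trial_label if trial_label else ''}")

    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"]).astype(bool)

    lx0, ly0, lx1, ly1 = geometry.aoi_left
    rx0, ry0, rx1, ry1 = geometry.aoi_right
    in_left = valid & (x >= lx0) & (x < lx1) & (y >= ly0) & (y < ly1)
    in_right = valid & (x >= rx0) & (x < rx1) & (y >= ry0) & (y < ry1)
    label = np.zeros(t.size, dtype=np.int8)
    label[in_left] = 1
    label[in_right] = 2

    period = geometry.sample_period_ms
    dwells: list[DwellRecord] = []
    cur_side = 0
    cur_start = cur_last = 0.0
    for i in range(t.size):
        li = label[i]
        if cur_side != 0:
            if li == cur_side and t[i] - cur_last <= max_gap_ms + period + 1e-6:
                cur_last = t[i]
                continue
            if li == 0 and t[i] - cur_last <= max_gap_ms:
                continue  # tolerable gap; wait for the next labelled sample
            # close the current dwell
            dur = cur_last + period - cur_start
            if dur >= min_dwell_ms:
                dwells.append(DwellRecord("left" if cur_side == 1 else "right",
                                          cur_start, cur_last + period))
            cur_side = 0
        if li != 0:
            cur_side = li
            cur_start = cur_last = t[i]
    if cur_side != 0:
        dur = cur_last + period - cur_start
        if dur >= min_dwell_ms:
            dwells.append(DwellRecord("left" if cur_side == 1 else "right",
                                      cur_start, cur_last + period))
    return dwells


def log_time_ratio(t_right_ms: float, t_left_ms: float, eps_ms: float = 1000.0 / 60.0) -> float:
    """log((T_R + eps) / (T_L + eps)); eps defaults to one sample period so a
    zero dwell counts as the smallest measurable one."""
    if t_right_ms < 0 or t_left_ms < 0:
        raise ValueError("dwell times must be nonnegative")
    return math.log((t_right_ms + eps_ms) / (t_left_ms + eps_ms))


def _overlap(dwell: DwellRecord, iv: Interval) -> float:
    return max(0.0, min(dwell.end_ms, iv.end_ms) - max(dwell.start_ms, iv.start_ms))


def compute_trial_metrics(
    dwells: Sequence[DwellRecord],
    intervals: Sequence[Interval],
    selected_side: Optional[str],
    eps_ms: float = 1000.0 / 60.0,
) -> pd.DataFrame:
    """Per-interval observation times and change-of-target metrics.

    Dwell durations are clipped to each interval before summation. A change of
    target (two adjacent dwells on different sides) is counted in the interval
    where the *second* dwell begins. Zero-length intervals yield NaN metrics
    rather than divisions by zero; t_selected_frac is NaN when no side was
    selected.
    """
    for a, b in zip(dwells, dwells[1:]):
        if b.start_ms < a.end_ms - 1e-6:  # tolerance for float round-off
            raise ValueError("dwells must be ordered and non-overlapping")
    rows = []
    for iv in intervals:
        if iv.duration_ms <= 0:
            rows.append({"interval": iv.name, "t_left_ms": np.nan, "t_right_ms": np.nan,
                         "t_selected_frac": np.nan, "n_cot": np.nan, "f_cot": np.nan,
                         "log_ratio": np.nan})
            continue
        t_left = sum(_overlap(d, iv) for d in dwells if d.side == "left")
        t_right = sum(_overlap(d, iv) for d in dwells if d.side == "right")
        n_cot = sum(
            1 for a, b in zip(dwells, dwells[1:])
            if a.side != b.side and iv.start_ms <= b.start_ms < iv.end_ms
        )
        f_cot = n_cot / (iv.duration_ms / 1000.0)
        if selected_side in ("left", "right"):
            t_sel = t_left if selected_side == "left" else t_right
            frac = t_sel / iv.duration_ms
        else:
            frac = np.nan
        rows.append({"interval": iv.name, "t_left_ms": t_left, "t_right_ms": t_right,
                     "t_selected_frac": frac, "n_cot": n_cot, "f_cot": f_cot,
                     "log_ratio": log_time_ratio(t_right, t_left, eps_ms)})
    return pd.DataFrame(rows)


def exclude_trials(trials: pd.DataFrame, max_dt_ms: float = 4000.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-exclusion rule: drop trials with a negative response
    time, a response time strictly longer than ``max_dt_ms``, or no response.

    Returns (kept trials, exclusion report with per-participant counts by
    reason).
    """
    dt = pd.to_numeric(trials["decision_time_ms"], errors="coerce")
    no_resp = dt.isna() | (trials["button"] == "none")
    negative = ~no_resp & (dt < 0)
    too_long = ~no_resp & (dt > max_dt_ms)
    excluded = no_resp | negative | too_long

    reason = pd.Series("kept", index=trials.index)
    reason[no_resp] = "no_response"
    reason[negative] = "negative_dt"
    reason[too_long] = "dt_too_long"
    report = (
        trials.assign(reason=reason)
        .groupby(["participant_id", "reason"], observed=True)
        .size()
        .rename("n_trials")
        .reset_index()
    )
    return trials.loc[~excluded].copy(), report


def intervals_for_trial(trial: pd.Series, stim_off_ms: float = 4000.0) -> list[Interval]:
    """The three analysis intervals of one trial, on the stimulus-onset clock:
    SOn = [0, GO), SOffUD = [GO, decision), SOffPD = [decision, GO + stim_off).
    Non-response trials get SOffUD spanning the full response window and an
    empty SOffPD. The Stimulus-On analogues of the always-visible variant map
    onto the same names."""
    go = float(trial["go_time_ms"])
    dt = trial.get("decision_time_ms", np.nan)
    end = go + stim_off_ms
    decision = go + float(dt) if pd.notna(dt) else end
    return [
        Interval("SOn", 0.0, go),
        Interval("SOffUD", go, min(decision, end)),
        Interval("SOffPD", min(decision, end), end),
    ]


def metrics_table(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    geometry: ScreenGeometry,
    min_dwell_ms: float = 100.0,
    max_gap_ms: float = 80.0,
    eps_ms: Optional[float] = None,
    stim_off_ms: float = 4000.0,
) -> pd.DataFrame:
    """One row per trial x interval: dwell times, #CoT, fCoT, log ratio.

    The selected side is derived from the pressed button (with the
    motor-reversal mapping where applicable).
    """
    from .simulate import selected_side_from_button

    if eps_ms is None:
        eps_ms = geometry.sample_period_ms
    grouped = dict(tuple(gaze.groupby(["participant_id", "trial_index"], sort=False)))
    out = []
    for _, tr in trials.iterrows():
        key = (tr["participant_id"], tr["trial_index"])
        stream = grouped.get(key)
        if stream is None:
            raise KeyError(f"no gaze stream for participant {key[0]} trial {key[1]}")
        dwells = extract_dwells(stream, geometry, min_dwell_ms, max_gap_ms,
                                trial_label=f"{key[0]}/{key[1]}")
        sel = selected_side_from_button(tr["button"], tr["experiment"])
        m = compute_trial_metrics(dwells, intervals_for_trial(tr, stim_off_ms), sel, eps_ms)
        m.insert(0, "trial_index", tr["trial_index"])
        m.insert(0, "participant_id", tr["participant_id"])
        out.append(m)
    return pd.concat(out, ignore_index=True)[METRICS_COLUMNS]
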