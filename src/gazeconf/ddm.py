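"""Drift-diffusion accounts of choice, decision time and confidence.

Two bounded-diffusion simulators (parallel: one constant drift equal to the
option-value difference; sequential: the drift is gated by which option is
currently attended) plus the closed-form confidence readouts of each account
and the three linear confidence observation models built on the attention
times dt1 (selected option) and dt2 (non-selected option).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .config import ConfidenceModelSpec, DDMParams

__all__ = [
    "SimTrace",
    "simulate_ddm_parallel",
    "simulate_ddm_sequential",
    "confidence_parallel",
    "confidence_sequential",
    "predict_confidence",
    "fp_prob_upper",
]


@dataclass
class SimTrace:
    """Outcome of one bounded-diffusion run.

    ``choice`` is "option1" when the upper bound +theta is hit first,
    "option2" for the lower bound, and None if no bound is hit within the
    simulation horizon. ``dt1_s``/``dt2_s`` are the total attention times per
    option up to the decision (sequential simulator only; for the parallel
    simulator they are split from the supplied schedule when one is given).
    """

    choice: Optional[str]
    decision_time_s: Optional[float]
    dt1_s: float = 0.0
    dt2_s: float = 0.0
    dx1: float = 0.0
    dx2: float = 0.0
    times_s: Optional[np.ndarray] = field(default=None, repr=False)
    x: Optional[np.ndarray] = field(default=None, repr=False)
    attended: Optional[np.ndarray] = field(default=None, repr=False)


def _check_step(params: DDMParams) -> None:
    # coarse steps bias first-passage estimates; warn rather than fail
    if params.dt_ms / 1000.0 > 0.01 * (params.theta / params.sigma) ** 2:
        warnings.warn(
            "integration step is large relative to (theta/sigma)^2; "
            "first-passage estimates may be biased",
            RuntimeWarning,
            stacklevel=3,
        )


def _first_crossing(x: np.ndarray, theta: float) -> Optional[int]:
    hits = np.flatnonzero(np.abs(x) >= theta)
    return int(hits[0]) if hits.size else None


def _integrate(drift: np.ndarray, params: DDMParams, rng: np.random.Generator,
               keep_path: bool) -> tuple[Optional[int], np.ndarray]:
    """Euler-Maruyama integration with the given per-step drift (1/s)."""
    dt_s = params.dt_ms / 1000.0
    n = drift.size
    incr = drift * dt_s + params.sigma * math.sqrt(dt_s) * rng.standard_normal(n)
    x = np.cumsum(incr)
    idx = _first_crossing(x, params.theta)
    return idx, x if keep_path else x[: (idx + 1) if idx is not None else n]


def simulate_ddm_parallel(
    params: DDMParams,
    rng: np.random.Generator | int | None = None,
    max_time_s: float = 8.0,
    keep_path: bool = False,
) -> SimTrace:
    """Constant-drift diffusion from x(0)=0 to the first crossing of +/-theta.

    The drift is params.mu = mu1 - mu2. Runs past ``max_time_s`` yield
    choice=None.
    """
    rng = np.random.default_rng(rng)
    _check_step(params)
    n = int(round(max_time_s * 1000.0 / params.dt_ms))
    drift = np.full(n, params.mu)
    idx, x = _integrate(drift, params, rng, keep_path)
    dt_s = params.dt_ms / 1000.0
    if idx is None:
        return SimTrace(None, None,
                        times_s=(np.arange(1, n + 1) * dt_s if keep_path else None),
                        x=(x if keep_path else None))
    t = (idx + 1) * dt_s
    choice = "option1" if x[idx] >= params.theta else "option2"
    return SimTrace(choice, t,
                    times_s=(np.arange(1, n + 1) * dt_s if keep_path else None),
                    x=(x if keep_path else None))


def _drift_from_schedule(schedule: Sequence[tuple[str, float, float]],
                         horizon_ms: float, dt_ms: float,
                         mu1: float, mu2: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-step drift and attended-option label from (side, start_ms, end_ms)
    dwell segments; option 1 is the 'left'/'option1' side. Steps outside any
    dwell (saccade gaps) carry zero drift and no attended option."""
    n = int(round(horizon_ms / dt_ms))
    drift = np.zeros(n)
    attended = np.zeros(n, dtype=np.int8)  # 0 none, 1 option1, 2 option2
    for side, start, end in schedule:
        i0 = int(math.ceil(start / dt_ms))
        i1 = min(int(math.ceil(end / dt_ms)), n)
        if i1 <= i0:
            continue
        if side in ("left", "option1"):
            drift[i0:i1] = mu1
            attended[i0:i1] = 1
        else:
            drift[i0:i1] = -mu2
            attended[i0:i1] = 2
    return drift, attended


def simulate_ddm_sequential(
    params: DDMParams,
    schedule: Sequence[tuple[str, float, float]],
    rng: np.random.Generator | int | None = None,
    max_time_s: Optional[float] = None,
    keep_path: bool = False,
    bounded: bool = True,
) -> SimTrace:
    """Attention-gated diffusion: drift +mu1 while option 1 (left) is attended,
    -mu2 while option 2 is, zero during saccade gaps.

    ``schedule`` is a sequence of (side, start_ms, end_ms) dwell segments.
    dt1/dt2 and dx1/dx2 accumulate attended time and evidence per option up to
    the decision (or the whole horizon when unbounded / no crossing).
    With ``bounded=False`` the walk never stops (used for drift diagnostics).
    """
    rng = np.random.default_rng(rng)
    _check_step(params)
    horizon_ms = max_time_s * 1000.0 if max_time_s is not None else max(e for _, _, e in schedule)
    drift, attended = _drift_from_schedule(schedule, horizon_ms, params.dt_ms, params.mu1, params.mu2)
    dt_s = params.dt_ms / 1000.0
    n = drift.size
    incr = drift * dt_s + params.sigma * math.sqrt(dt_s) * rng.standard_normal(n)
    x = np.cumsum(incr)
    idx = _first_crossing(x, params.theta) if bounded else None

    upto = n if idx is None else idx + 1
    m1 = attended[:upto] == 1
    m2 = attended[:upto] == 2
    trace = SimTrace(
        choice=None,
        decision_time_s=None,
        dt1_s=float(m1.sum()) * dt_s,
        dt2_s=float(m2.sum()) * dt_s,
        dx1=float(incr[:upto][m1].sum()),
        dx2=float(-incr[:upto][m2].sum()),  # evidence for option 2 accrues as -dx
        times_s=(np.arange(1, n + 1) * dt_s if keep_path else None),
        x=(x if keep_path else None),
        attended=(attended if keep_path else None),
    )
    if idx is not None:
        trace.choice = "option1" if x[idx] >= params.theta else "option2"
        trace.decision_time_s = (idx + 1) * dt_s
    return trace


def confidence_parallel(theta: float, sigma: float, t_s, scaling: str = "sqrt"):
    """Parallel-account decision confidence g(t) = Phi(theta / sigma(t)).

    The accumulated-noise scale is sigma*sqrt(t) by default ('sqrt'); a
    'linear' sigma*t variant is exposed for sensitivity analyses. Confidence
    depends on the decision time alone, decreasing in t and tending to 1 as
    t -> 0+.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t <= 0):
        raise ValueError("decision time must be positive")
    denom = sigma * np.sqrt(t) if scaling == "sqrt" else sigma * t
    out = norm.cdf(theta / denom)
    return float(out) if np.isscalar(t_s) else out


def confidence_sequential(mu0: float, sigma: float, dt1_s, dt2_s):
    """Sequential-account confidence: logistic in the attention-time
    difference, g = 1 / (1 + exp(-2*mu0*(dt1 - dt2)/sigma^2)).

    Depends only on dt1 - dt2, never on the total dt1 + dt2; equals exactly
    one half when the two observation times are equal.
    """
    d = np.asarray(dt1_s, dtype=float) - np.asarray(dt2_s, dtype=float)
    out = 1.0 / (1.0 + np.exp(-2.0 * mu0 * d / sigma**2))
    return float(out) if np.isscalar(dt1_s) and np.isscalar(dt2_s) else out


def predict_confidence(spec: ConfidenceModelSpec, dt1_s, dt2_s):
    """Linear confidence prediction of the named observation model.

    No clipping is applied here; the synthetic generator clips to [0, 1]
    before adding reporting noise.
    """
    dt1 = np.asarray(dt1_s, dtype=float)
    dt2 = np.asarray(dt2_s, dtype=float)
    total = dt1 + dt2
    if spec.name in ("parallel", "hybrid") and np.any(total <= 0):
        raise ValueError("total observation time must be positive for the inverse-time term")
    if spec.name == "parallel":
        out = spec.alpha0 + spec.alpha1 / total
    elif spec.name == "sequential":
        out = spec.alpha0 + spec.alpha1 * (dt1 - dt2)
    else:
        out = spec.alpha0 + spec.alpha1 * (dt1 - dt2) + spec.alpha2 / total
    return float(out) if np.isscalar(dt1_s) and np.isscalar(dt2_s) else out


def fp_prob_upper(mu: float, sigma: float, theta: float) -> float:
    """First-passage probability of the upper bound for a constant-drift
    diffusion started at 0 between symmetric bounds: 1/(1+exp(-2*mu*theta/sigma^2)).

    Validation oracle for the simulators.
    """
    if sigma <= 0 or theta <= 0:
        raise ValueError("sigma and theta must be positive")
    return 1.0 / (1.0 + math.exp(-2.0 * mu * theta / sigma**2))
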