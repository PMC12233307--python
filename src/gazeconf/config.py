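"""Domain types and configuration objects shared across the pipeline.

Times are milliseconds unless a name says otherwise (``*_s`` suffixes are
seconds; diffusion parameters are per-second / per-sqrt-second). Screen
coordinates are pixels with the origin at the top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

#: axis-aligned rectangle (x0, y0, x1, y1) in pixels, half-open on the right/bottom
Rect = tuple[float, float, float, float]

EXPERIMENTS = ("LAN", "LAS", "rLAN", "sLAN")
MODEL_NAMES = ("hybrid", "sequential", "parallel")
INTERVALS = ("SOn", "SOffUD", "SOffPD")


def _rect_ok(r: Rect) -> bool:
    return len(r) == 4 and r[0] < r[2] and r[1] < r[3]


def _rects_disjoint(a: Rect, b: Rect) -> bool:
    return a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]


def _default_aoi(center_x: float, center_y: float,
                 half_w: float = 157.5, half_h: float = 153.0) -> Rect:
    # image frame 265x256 px padded by 25 px on each side
    return (center_x - half_w, center_y - half_h, center_x + half_w, center_y + half_h)


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen and area-of-interest layout of the two lateral option images."""

    width_px: int = 1920
    height_px: int = 1080
    aoi_left: Rect = field(default_factory=lambda: _default_aoi(480.0, 540.0))
    aoi_right: Rect = field(default_factory=lambda: _default_aoi(1440.0, 540.0))
    sample_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name, r in (("aoi_left", self.aoi_left), ("aoi_right", self.aoi_right)):
            if not _rect_ok(r):
                raise ValueError(f"{name} is not a valid rectangle: {r}")
            if r[0] < 0 or r[1] < 0 or r[2] > self.width_px or r[3] > self.height_px:
                raise ValueError(f"{name} extends outside the screen")
        if not _rects_disjoint(self.aoi_left, self.aoi_right):
            raise ValueError("AOIs overlap")

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def aoi_center(self, side: str) -> tuple[float, float]:
        r = self.aoi_left if side == "left" else self.aoi_right
        return ((r[0] + r[2]) / 2.0, (r[1] + r[3]) / 2.0)

    def aoi_side(self, x: float, y: float) -> Optional[str]:
        """Which AOI contains (x, y), or None."""
        for side, r in (("left", self.aoi_left), ("right", self.aoi_right)):
            if r[0] <= x < r[2] and r[1] <= y < r[3]:
                return side
        return None


@dataclass(frozen=True)
class TrialTimeline:
    """Phase durations of one trial.

    The decision phases are Stimulus-On (both option images shown), then at the
    GO signal Stimulus-Off (images removed, frames left behind) during which the
    choice is reported within ``response_window_ms``.
    """

    fixation1_ms: float = 1000.0
    context_ms: float = 4000.0
    fixation2_ms: float = 1000.0
    stim_on_ms: float = 4000.0
    stim_off_ms: float = 4000.0
    response_window_ms: float = 4000.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.response_window_ms > self.stim_off_ms:
            raise ValueError("response_window_ms cannot exceed stim_off_ms")

    @property
    def go_time_ms(self) -> float:
        """GO signal, on the clock whose origin is stimulus onset."""
        return self.stim_on_ms

    @property
    def decision_span_ms(self) -> float:
        """Stimulus onset to end of the Stimulus-Off interval."""
        return self.stim_on_ms + self.stim_off_ms

    @classmethod
    def for_experiment(cls, experiment: str) -> "TrialTimeline":
        if experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
        return cls(stim_on_ms=2000.0) if experiment == "sLAN" else cls()


@dataclass(frozen=True)
class DDMParams:
    """Bounded diffusion parameters.

    ``mu1``/``mu2`` are the two option values (drift contributions, 1/s);
    the parallel model integrates the constant drift mu = mu1 - mu2, the
    sequential model integrates +mu1 while option 1 is attended and -mu2
    while option 2 is. ``sigma`` is the diffusion noise scale (1/sqrt(s)),
    ``theta`` the symmetric bound magnitude, ``dt_ms`` the Euler step.
    """

    mu1: float = 0.15
    mu2: float = 0.15
    sigma: float = 0.5
    theta: float = 1.0
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def mu(self) -> float:
        """Net drift of the parallel model."""
        return self.mu1 - self.mu2

    @classmethod
    def symmetric(cls, mu0: float, **kw) -> "DDMParams":
        """Equal-magnitude, opposite-sign option values mu1 = -mu2 = mu0/2."""
        return cls(mu1=mu0 / 2.0, mu2=-mu0 / 2.0, **kw)


@dataclass(frozen=True)
class ConfidenceModelSpec:
    """One of the three linear confidence observation models.

    parallel:    C = alpha0 + alpha1 / (dt1 + dt2)
    sequential:  C = alpha0 + alpha1 * (dt1 - dt2)
    hybrid:      C = alpha0 + alpha1 * (dt1 - dt2) + alpha2 / (dt1 + dt2)

    with dt1/dt2 the observation times (seconds) of the selected and
    non-selected option.
    """

    name: str = "hybrid"
    alpha0: float = 0.5
    alpha1: float = 0.15
    alpha2: Optional[float] = 0.3

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if self.name == "hybrid" and self.alpha2 is None:
            raise ValueError("hybrid model requires alpha2")
        if self.name in ("sequential", "parallel") and self.alpha2 not in (None, 0.0):
            raise ValueError(f"{self.name} model takes no alpha2")

    @property
    def n_params(self) -> int:
        return 3 if self.name == "hybrid" else 2


@dataclass(frozen=True)
class GenerativeConfig:
    """Everything the synthetic-experiment generator needs.

    The defaults are the study conditions the pipeline is validated under:
    80 trials per participant, 4 s / 2 s (sLAN) Stimulus-On, alternating
    gamma-distributed dwells calibrated to ~1.3 Hz alternation during
    Stimulus-On, and confidence generated from the named observation model
    plus Gaussian reporting noise before rounding to the [0, scale_max] scale.
    """

    n_participants: int = 20
    n_trials: int = 80
    experiment: str = "LAN"
    model: str = "hybrid"
    ddm: DDMParams = field(default_factory=DDMParams)
    alpha: ConfidenceModelSpec = field(default_factory=ConfidenceModelSpec)
    value_mean: float = 0.15       # mean option value (1/s), truncated normal at 0
    value_sd: float = 0.10
    dwell_mean_ms: float = 730.0
    dwell_shape: float = 4.0
    saccade_gap_ms: float = 40.0
    jitter_sd_px: float = 25.0
    motor_latency_mean_ms: float = 300.0
    motor_latency_sd_ms: float = 50.0
    post_commit_off_prob: float = 0.5  # chance a post-commitment pre-GO dwell leaves the AOIs
    rating_noise_sd: float = 0.05
    rating_scale_max: int = 10
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_trials <= 0:
            raise ValueError("n_participants and n_trials must be positive")
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model != self.alpha.name:
            raise ValueError("cfg.model and cfg.alpha.name must agree")
        if self.dwell_mean_ms <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell parameters must be positive")
        if self.rating_scale_max not in (9, 10):
            raise ValueError("rating_scale_max must be 9 or 10")

    @property
    def timeline(self) -> TrialTimeline:
        return TrialTimeline.for_experiment(self.experiment)


@dataclass(frozen=True)
class EvidenceConfig:
    """Prior and noise model of the Bayesian linear inversion of the
    confidence models (the per-participant log evidence / free energy)."""

    prior_sd_alpha: float = 5.0
    noise_model: str = "conjugate"   # or "fixed_sd"
    noise_sd: Optional[float] = None  # required for fixed_sd
    a0: float = 1e-3                 # inverse-gamma shape (conjugate noise prior)
    b0: float = 1e-3                 # inverse-gamma scale
    standardize_predictors: bool = True

    def __post_init__(self) -> None:
        if self.prior_sd_alpha <= 0:
            raise ValueError("prior_sd_alpha must be positive")
        if self.noise_model not in ("conjugate", "fixed_sd"):
            raise ValueError("noise_model must be 'conjugate' or 'fixed_sd'")
        if self.noise_model == "fixed_sd" and (self.noise_sd is None or self.noise_sd <= 0):
            raise ValueError("fixed_sd noise model requires positive noise_sd")


def generative_config_from_json(path: str | Path) -> GenerativeConfig:
    """Load a GenerativeConfig from a JSON document mirroring its fields."""
    doc = json.loads(Path(path).read_text())
    if "ddm" in doc:
        doc["ddm"] = DDMParams(**doc["ddm"])
    if "alpha" in doc:
        doc["alpha"] = ConfidenceModelSpec(**doc["alpha"])
    if "geometry" in doc:
        geo = dict(doc["geometry"])
        for k in ("aoi_left", "aoi_right"):
            if k in geo:
                geo[k] = tuple(geo[k])
        doc["geometry"] = ScreenGeometry(**geo)
    return GenerativeConfig(**doc)
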