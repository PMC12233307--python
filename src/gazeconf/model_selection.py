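"""Inversion of the three confidence observation models and random-effects
Bayesian model selection.

Each model (hybrid / sequential / parallel) is a linear regression of the
normalized confidence report y = C / scale_max on functions of the attention
times dt1 (selected option) and dt2 (non-selected option), measured over the
evidence-gathering span (Stimulus-On plus Stimulus-Off until the decision).
Because the models are linear-Gaussian, the per-participant log model
evidence (free energy) is available in closed form — with a Gaussian prior on
the coefficients and either a fixed noise SD or a conjugate inverse-gamma
noise prior — so no variational approximation is needed (the bound is tight).

The participants x models log-evidence matrix feeds a random-effects analysis:
models are treated as random effects with an unknown population distribution,
yielding a Dirichlet posterior over model frequencies; the exceedance
probability of a model is the posterior probability that it is more frequent
than every competitor, estimated from seeded Dirichlet draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .config import MODEL_NAMES, EvidenceConfig, GenerativeConfig

__all__ = [
    "BMSResult",
    "model_design",
    "attention_times",
    "log_evidence_linear",
    "posterior_coefficients",
    "invert_participants",
    "rfx_bms",
    "model_recovery",
]

DESIGN_COLUMNS = {
    "hybrid": ["const", "dt_diff_s", "inv_total_s"],
    "sequential": ["const", "dt_diff_s"],
    "parallel": ["const", "inv_total_s"],
}


@dataclass(frozen=True)
class BMSResult:
    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    model_frequency: np.ndarray    # Dirichlet mean alpha_k / sum(alpha)
    exceedance_prob: np.ndarray
    n_dirichlet_samples: int
    seed: int | None
    n_iterations: int
    assignment: np.ndarray = field(default=None, repr=False)  # u_nk posterior

    def winner(self) -> str:
        return self.model_names[int(np.argmax(self.exceedance_prob))]


def attention_times(metrics: pd.DataFrame, trials: pd.DataFrame,
                    intervals: tuple[str, ...] = ("SOn", "SOffUD")) -> pd.DataFrame:
    """Per-trial attention times dt1 (selected option) / dt2 (other option) in
    seconds, summed over the evidence-gathering intervals."""
    from .simulate import selected_side_from_button

    m = metrics[metrics["interval"].isin(intervals)]
    agg = m.groupby(["participant_id", "trial_index"])[["t_left_ms", "t_right_ms"]].sum()
    tr = trials.set_index(["participant_id", "trial_index"])
    sel = tr.apply(lambda r: selected_side_from_button(r["button"], r["experiment"]), axis=1)
    joined = agg.join(sel.rename("selected"), how="inner")
    joined = joined[joined["selected"].isin(["left", "right"])]
    left_sel = joined["selected"] == "left"
    dt1 = np.where(left_sel, joined["t_left_ms"], joined["t_right_ms"]) / 1000.0
    dt2 = np.where(left_sel, joined["t_right_ms"], joined["t_left_ms"]) / 1000.0
    out = pd.DataFrame({"dt1_s": dt1, "dt2_s": dt2}, index=joined.index)
    return out.reset_index()


def model_design(data: pd.DataFrame, model: str, scale_max: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and response for one participant and one model.

    ``data`` holds one row per trial with dt1_s, dt2_s and the confidence
    rating C. The response is C / scale_max; predictors are an intercept,
    (dt1 - dt2) in seconds and/or 1 / (dt1 + dt2) in 1/s. Trials with zero
    total time are dropped when an inverse-time term is present.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    d = data.dropna(subset=["dt1_s", "dt2_s", "C"]).copy()
    total = d["dt1_s"] + d["dt2_s"]
    if model in ("hybrid", "parallel"):
        d = d[total > 0]
        total = total[total > 0]
    cols = {"const": np.ones(len(d))}
    if model in ("hybrid", "sequential"):
        cols["dt_diff_s"] = (d["dt1_s"] - d["dt2_s"]).to_numpy()
    if model in ("hybrid", "parallel"):
        cols["inv_total_s"] = (1.0 / total).to_numpy()
    X = pd.DataFrame(cols)[DESIGN_COLUMNS[model]]
    y = d["C"].to_numpy(dtype=float) / scale_max
    return X, y


def _standardize(X: np.ndarray, columns: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score non-intercept columns; returns (Xz, means, sds) with
    means/sds equal to (0, 1) for the intercept."""
    Xz = X.copy()
    means = np.zeros(X.shape[1])
    sds = np.ones(X.shape[1])
    for j, name in enumerate(columns):
        if name == "const":
            continue
        mu, sd = X[:, j].mean(), X[:, j].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {name} is constant; cannot standardize")
        Xz[:, j] = (X[:, j] - mu) / sd
        means[j], sds[j] = mu, sd
    return Xz, means, sds


def _prep(X, y, cfg: EvidenceConfig):
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] <= Xa.shape[1]:
        raise ValueError("need more observations than predictors")
    if cfg.standardize_predictors:
        Xa, means, sds = _standardize(Xa, columns)
    else:
        means = np.zeros(Xa.shape[1])
        sds = np.ones(Xa.shape[1])
    return Xa, ya, columns, means, sds


def log_evidence_linear(X, y, cfg: EvidenceConfig = EvidenceConfig()) -> float:
    """Exact log marginal likelihood (nats) of the Bayesian linear model.

    Coefficients carry a zero-mean Gaussian prior of scale
    ``cfg.prior_sd_alpha``; the noise model is either a known SD
    (``fixed_sd``) or a conjugate inverse-gamma prior on the variance
    (normal-inverse-gamma marginal, in which the coefficient prior scale is
    relative to the noise SD). This is the free energy of the model, exact in
    the conjugate case.
    """
    Xa, ya, _, _, _ = _prep(X, y, cfg)
    n, p = Xa.shape
    s2 = cfg.prior_sd_alpha**2
    if cfg.noise_model == "fixed_sd":
        sig2 = cfg.noise_sd**2
        # y ~ N(0, sig2*I + s2*X X^T); evaluate via the p x p form
        A = np.eye(p) / s2 + Xa.T @ Xa / sig2
        La = np.linalg.cholesky(A)
        Xty = Xa.T @ ya / sig2
        z = np.linalg.solve(La, Xty)
        quad = ya @ ya / sig2 - z @ z
        logdet = n * np.log(sig2) + p * np.log(s2) + 2.0 * np.log(np.diag(La)).sum()
        return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))
    # conjugate normal-inverse-gamma
    V0_inv = np.eye(p) / s2
    Vn_inv = V0_inv + Xa.T @ Xa
    L = np.linalg.cholesky(Vn_inv)
    z = np.linalg.solve(L, Xa.T @ ya)
    an = cfg.a0 + n / 2.0
    bn = cfg.b0 + 0.5 * (ya @ ya - z @ z)
    logdet_ratio = -2.0 * np.log(np.diag(L)).sum() - p * np.log(s2)  # log|Vn| - log|V0|
    return float(
        -0.5 * n * np.log(2.0 * np.pi)
        + 0.5 * logdet_ratio
        + cfg.a0 * np.log(cfg.b0) - an * np.log(bn)
        + gammaln(an) - gammaln(cfg.a0)
    )


def posterior_coefficients(X, y, cfg: EvidenceConfig = EvidenceConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the coefficients on the ORIGINAL
    predictor scale (standardization, if configured, is undone)."""
    Xa, ya, columns, means, sds = _prep(X, y, cfg)
    n, p = Xa.shape
    s2 = cfg.prior_sd_alpha**2
    if cfg.noise_model == "fixed_sd":
        sig2 = cfg.noise_sd**2
        Vn = np.linalg.inv(np.eye(p) / s2 + Xa.T @ Xa / sig2)
        mean_z = Vn @ (Xa.T @ ya) / sig2
        cov_z = Vn
    else:
        Vn = np.linalg.inv(np.eye(p) / s2 + Xa.T @ Xa)
        mean_z = Vn @ (Xa.T @ ya)
        an = cfg.a0 + n / 2.0
        bn = cfg.b0 + 0.5 * (ya @ ya - mean_z @ (Xa.T @ ya))
        cov_z = Vn * (bn / (an - 1.0))  # marginal t covariance
    # de-standardize: beta_orig = A @ beta_z with A mapping z-scale to raw scale
    A = np.zeros((p, p))
    try:
        i0 = columns.index("const")
    except ValueError:
        i0 = None
    for j in range(p):
        if j == i0:
            A[j, j] = 1.0
        else:
            A[j, j] = 1.0 / sds[j]
            if i0 is not None:
                A[i0, j] = -means[j] / sds[j]
    mean = A @ mean_z
    cov = A @ cov_z @ A.T
    return mean, cov


def invert_participants(att: pd.DataFrame, trials: pd.DataFrame,
                        cfg: EvidenceConfig = EvidenceConfig(),
                        scale_max: int = 10,
                        models: tuple[str, ...] = tuple(MODEL_NAMES)) -> pd.DataFrame:
    """Free-energy table: one row per participant, one column per model.

    ``att`` is the attention_times table; confidence ratings are joined from
    ``trials``.
    """
    data = att.merge(trials[["participant_id", "trial_index", "C"]],
                     on=["participant_id", "trial_index"], how="inner")
    rows = {}
    for pid, grp in data.groupby("participant_id"):
        rows[pid] = {m: log_evidence_linear(*model_design(grp, m, scale_max), cfg)
                     for m in models}
    F = pd.DataFrame.from_dict(rows, orient="index")[list(models)]
    F.index.name = "participant_id"
    return F


def rfx_bms(
    F,
    alpha0=(1.0, 1.0, 1.0),
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_dirichlet_samples: int = 1_000_000,
    seed: int | None = None,
) -> BMSResult:
    """Random-effects Bayesian model selection over a participants x models
    log-evidence matrix.

    Iterates the standard variational update — per participant,
    u_nk proportional to exp(F_nk + psi(alpha_k) - psi(sum alpha)); then
    alpha_k = alpha0_k + sum_n u_nk — to convergence. Model frequencies are
    the Dirichlet mean alpha / sum(alpha); exceedance probabilities are the
    fraction of seeded Dirichlet(alpha) draws in which each model's frequency
    is the largest. Only within-participant evidence differences matter
    (row-shift invariant).
    """
    if isinstance(F, pd.DataFrame):
        names = tuple(F.columns)
        Fa = F.to_numpy(dtype=float)
    else:
        Fa = np.asarray(F, dtype=float)
        names = tuple(f"model{k}" for k in range(Fa.shape[1]))
    if not np.all(np.isfinite(Fa)):
        raise ValueError("free energies must be finite")
    n, K = Fa.shape
    a0 = np.asarray(alpha0, dtype=float)
    if a0.shape != (K,):
        raise ValueError("alpha0 length must match the number of models")

    alpha = a0.copy()
    Fc = Fa - Fa.max(axis=1, keepdims=True)  # row shift, for numerical safety
    u = None
    for it in range(1, max_iter + 1):
        logu = Fc + (digamma(alpha) - digamma(alpha.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(f"RFX-BMS did not converge in {max_iter} iterations; "
                           f"last alpha={alpha}")

    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_dirichlet_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_dirichlet_samples
    return BMSResult(names, alpha, freq, xp, n_dirichlet_samples, seed, it, assignment=u)


def model_recovery(
    base_cfg: GenerativeConfig,
    evidence_cfg: EvidenceConfig = EvidenceConfig(),
    seed: int = 0,
    generative_models: tuple[str, ...] = tuple(MODEL_NAMES),
    n_dirichlet_samples: int = 100_000,
) -> pd.DataFrame:
    """Confusion table of the RFX-BMS winner (by exceedance probability) per
    generative model: simulate a cohort from each model, run the full
    inversion and selection, and tabulate which model wins."""
    from dataclasses import replace

    from .config import ConfidenceModelSpec
    from .gaze import exclude_trials, metrics_table
    from .simulate import simulate_dataset

    rows = []
    for i, gen in enumerate(generative_models):
        if gen == "hybrid":
            alpha = ConfidenceModelSpec("hybrid", 0.5, 0.15, 0.3)
        elif gen == "sequential":
            alpha = ConfidenceModelSpec("sequential", 0.5, 0.15, None)
        else:
            alpha = ConfidenceModelSpec("parallel", 0.5, 0.3, None)
        cfg = replace(base_cfg, model=gen, alpha=alpha, seed=seed + i)
        gaze, trials, _ = simulate_dataset(cfg)
        kept, _ = exclude_trials(trials)
        metrics = metrics_table(gaze, kept, cfg.geometry)
        att = attention_times(metrics, kept)
        F = invert_participants(att, kept, evidence_cfg, cfg.rating_scale_max)
        res = rfx_bms(F, n_dirichlet_samples=n_dirichlet_samples, seed=seed + 100 + i)
        row = {"generative_model": gen, "winner": res.winner()}
        row.update({f"xp_{m}": res.exceedance_prob[j] for j, m in enumerate(res.model_names)})
        rows.append(row)
    return pd.DataFrame(rows)
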