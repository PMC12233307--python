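"""Psychometric analysis of choice vs looking-time ratio.

Per participant and interval, trials are ranked by the log right/left
observation-time ratio and split into four equal-count quartile bins; the
proportion of right-button choices per bin is fitted with the logistic

    P_R = 1 / (1 + exp(-(beta0 + beta1 * log(T_R / T_L))))

by binomial maximum likelihood on the four points. Per-participant
significance uses a permutation scheme: the four (proportion, count) pairs are
shuffled across the four quartile positions 10,000 times, the slope refitted,
and the observed slope declared significant when it exceeds the 95th
percentile of the shuffle distribution. Group-level comparisons are t-tests
with JZS (Cauchy-prior) Bayes factors, plus a two-sample KS test for
decision-time distributions and per-participant confidence/decision-time
Pearson correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "QuartileBin",
    "PsychometricFit",
    "GroupTestResult",
    "quartile_bins",
    "fit_logistic",
    "fit_logistic_batch",
    "permutation_test_beta1",
    "group_ttest",
    "jzs_bayes_factor",
    "compare_dt_distributions",
    "correlate_confidence_dt",
    "fit_participant_interval",
]


@dataclass(frozen=True)
class QuartileBin:
    x_q: float   # representative (median) log-ratio of the bin
    p_q: float   # proportion of right choices
    n_q: int     # trial count

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_q <= 1.0:
            raise ValueError("p_q must lie in [0, 1]")
        if self.n_q < 1:
            raise ValueError("n_q must be at least 1")


@dataclass(frozen=True)
class PsychometricFit:
    beta0: float
    beta1: float
    deviance: float
    perm_p: Optional[float] = None
    significant: Optional[bool] = None
    separation_flag: bool = False


@dataclass(frozen=True)
class GroupTestResult:
    t_stat: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    bf01: Optional[float] = None


def quartile_bins(log_ratios: Sequence[float], right_choice: Sequence[bool]) -> list[QuartileBin]:
    """Rank trials by log-ratio and split into 4 equal-count bins (remainder
    goes to the lower bins); x_q is the within-bin median log-ratio, p_q the
    fraction of right choices."""
    x = np.asarray(log_ratios, dtype=float)
    r = np.asarray(right_choice, dtype=bool)
    if x.size != r.size:
        raise ValueError("log_ratios and right_choice lengths differ")
    if x.size < 8:
        raise ValueError(f"need at least 8 trials to form quartiles, got {x.size}")
    order = np.argsort(x, kind="stable")
    n = x.size
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    bins, start = [], 0
    for sz in sizes:
        idx = order[start:start + sz]
        start += sz
        bins.append(QuartileBin(float(np.median(x[idx])), float(r[idx].mean()), int(sz)))
    return bins


def _newton_logistic(x: np.ndarray, k: np.ndarray, n: np.ndarray,
                     beta1_max: float, n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton maximization of the binomial log-likelihood of the
    two-parameter logistic, batched over the leading axis.

    x, k, n: (m, q) arrays of bin positions, success counts (may be
    fractional) and trial counts. Returns (beta0, beta1), each (m,). The
    problem is convex, so Newton from the origin converges; slopes are clipped
    to +/- beta1_max (complete separation)."""
    m = x.shape[0]
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * x
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p) + 1e-12
        g0 = (n * p - k).sum(axis=1)
        g1 = ((n * p - k) * x).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01 + 1e-12
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        norm = np.maximum(1.0, np.sqrt(step0**2 + step1**2) / 4.0)  # damp big steps
        b0 -= step0 / norm
        b1 -= step1 / norm
        np.clip(b0, -30.0, 30.0, out=b0)
        np.clip(b1, -beta1_max, beta1_max, out=b1)
    return b0, b1


def _bins_to_arrays(bins: Sequence[QuartileBin]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([b.x_q for b in bins], dtype=float)
    n = np.array([b.n_q for b in bins], dtype=float)
    k = np.array([b.p_q * b.n_q for b in bins], dtype=float)
    return x, k, n


def _deviance(x, k, n, b0, b1) -> float:
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = (k * np.log(p) + (n - k) * np.log(1 - p)).sum()
    ps = np.clip(k / n, 1e-12, 1 - 1e-12)
    ll_sat = (k * np.log(ps) + (n - k) * np.log(1 - ps)).sum()
    return float(2.0 * (ll_sat - ll))


def fit_logistic_batch(x: np.ndarray, k: np.ndarray, n: np.ndarray,
                       beta1_max: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Batched binomial-ML logistic fit; see _newton_logistic."""
    return _newton_logistic(np.atleast_2d(x), np.atleast_2d(k), np.atleast_2d(n), beta1_max)


def fit_logistic(bins: Sequence[QuartileBin], beta1_max: float = 20.0) -> PsychometricFit:
    """Fit the two-parameter logistic to the quartile points by binomial
    maximum likelihood. Deterministic given the bins; complete separation is
    reported by a capped slope and a flag."""
    x, k, n = _bins_to_arrays(bins)
    if not np.all(np.isfinite(x)):
        raise ValueError("bin positions must be finite")
    b0, b1 = _newton_logistic(x[None, :], k[None, :], n[None, :], beta1_max)
    b0f, b1f = float(b0[0]), float(b1[0])
    sep = abs(b1f) >= 0.999 * beta1_max
    return PsychometricFit(b0f, b1f, _deviance(x, k, n, b0f, b1f), separation_flag=sep)


_PERMS4 = np.array(list(itertools.permutations(range(4))))  # all 24 orderings


def permutation_test_beta1(
    bins: Sequence[QuartileBin],
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
    beta1_max: float = 20.0,
) -> PsychometricFit:
    """Permutation significance of the psychometric slope.

    The four (p_q, n_q) pairs are shuffled across the four x_q positions and
    the slope refitted; perm_p = (1 + #{beta1_shuffle >= beta1_obs}) /
    (n_shuffles + 1), and the slope is significant when it exceeds the 95th
    percentile of the shuffle distribution. With ``exact=True`` the 24
    possible orderings are enumerated with equal weight instead of sampled
    (perm_p = #{beta1_perm >= beta1_obs} / 24, the identity included).

    Since a shuffle of four points can only realise 24 distinct orderings,
    each ordering is fitted once and the sampled shuffles index into them;
    this is exactly equivalent to refitting every shuffle.
    """
    base = fit_logistic(bins, beta1_max)
    x, k, n = _bins_to_arrays(bins)
    xs = np.broadcast_to(x, (24, 4))
    ks = k[_PERMS4]
    ns = n[_PERMS4]
    _, b1_all = _newton_logistic(xs.copy(), ks, ns, beta1_max)

    if exact:
        perm_p = float((b1_all >= base.beta1 - 1e-12).mean())
        crit = np.quantile(b1_all, 0.95)
    else:
        rng = np.random.default_rng(seed)
        draws = b1_all[rng.integers(0, 24, size=n_shuffles)]
        perm_p = float((1 + (draws >= base.beta1 - 1e-12).sum()) / (n_shuffles + 1))
        crit = np.quantile(draws, 0.95)
    significant = bool(base.beta1 > crit + 1e-12)
    return PsychometricFit(base.beta0, base.beta1, base.deviance,
                           perm_p=perm_p, significant=significant,
                           separation_flag=base.separation_flag)


def group_ttest(
    values: Sequence[float],
    mu0: float = 0.0,
    other: Optional[Sequence[float]] = None,
    paired: bool = False,
    with_bf: bool = True,
) -> GroupTestResult:
    """One-sample (against mu0), paired, or two-sample t-test with a 95% CI
    and the JZS Bayes factor for the null."""
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 values")
    if other is None:
        if np.std(a, ddof=1) == 0:
            raise ValueError("zero variance")
        res = stats.ttest_1samp(a, popmean=mu0)
        n1, n2 = a.size, None
    elif paired:
        b = np.asarray(other, dtype=float)
        res = stats.ttest_rel(a, b)
        n1, n2 = a.size, None
    else:
        b = np.asarray(other, dtype=float)
        res = stats.ttest_ind(a, b, equal_var=True)
        n1, n2 = a.size, b.size
    ci = res.confidence_interval(0.95)
    bf01 = jzs_bayes_factor(float(res.statistic), n1, n2) if with_bf else None
    return GroupTestResult(float(res.statistic), float(res.df),
                           float(ci.low), float(ci.high), float(res.pvalue), bf01)


def jzs_bayes_factor(t_stat: float, n1: int, n2: Optional[int] = None,
                     prior_scale: float = math.sqrt(2) / 2.0) -> float:
    """JZS (Cauchy-prior) Bayes factor BF01 in favour of the null for a
    t-test.

    BF10 is the ratio of the marginal likelihood of t under a Cauchy(0, r)
    prior on the standardized effect size (noncentral-t integrand, integrated
    numerically) to the likelihood under delta = 0; BF01 = 1 / BF10. For two
    samples the effective sample size is n1*n2/(n1+n2) with df n1+n2-2.
    """
    if not math.isfinite(t_stat):
        raise ValueError("t statistic must be finite")
    if n2 is None:
        df, n_eff = n1 - 1, float(n1)
    else:
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    if df < 1:
        raise ValueError("not enough observations")

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t_stat, df, delta * math.sqrt(n_eff)) * \
            stats.cauchy.pdf(delta, scale=prior_scale)

    # split at the likelihood peak so quad never misses a far-from-zero mode
    peak = t_stat / math.sqrt(n_eff)
    cuts = sorted({0.0, peak})
    edges = [-np.inf, *cuts, np.inf]
    num = err = 0.0
    for lo, hi in zip(edges, edges[1:]):
        v, e = integrate.quad(integrand, lo, hi, limit=200)
        num += v
        err += e
    den = stats.t.pdf(t_stat, df)
    if not np.isfinite(num) or num <= 0 or err > 1e-3 * num:
        raise RuntimeError("Bayes-factor quadrature did not converge")
    return float(den / num)


def compare_dt_distributions(dt_a: Sequence[float], dt_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov comparison of decision-time samples."""
    a = np.asarray(dt_a, dtype=float)
    b = np.asarray(dt_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def correlate_confidence_dt(trials: pd.DataFrame, min_trials: int = 3,
                            fisher_z: bool = False) -> tuple[pd.DataFrame, GroupTestResult]:
    """Per-participant Pearson correlation between the reported confidence and
    the decision time, and a group t-test of the correlations against zero.

    Participants with fewer than ``min_trials`` valid trials or zero variance
    in either variable are skipped (flagged in the returned table).
    """
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        ok = grp["decision_time_ms"].notna()
        c = grp.loc[ok, "C"].to_numpy(dtype=float)
        dt = grp.loc[ok, "decision_time_ms"].to_numpy(dtype=float)
        if c.size < min_trials or np.std(c) == 0 or np.std(dt) == 0:
            rows.append({"participant_id": pid, "r": np.nan, "n": int(c.size), "skipped": True})
            continue
        r = stats.pearsonr(c, dt).statistic
        rows.append({"participant_id": pid, "r": float(r), "n": int(c.size), "skipped": False})
    table = pd.DataFrame(rows)
    rs = table.loc[~table["skipped"], "r"].to_numpy()
    vals = np.arctanh(np.clip(rs, -0.999999, 0.999999)) if fisher_z else rs
    group = group_ttest(vals, mu0=0.0)
    return table, group


def fit_participant_interval(
    metrics: pd.DataFrame,
    trials: pd.DataFrame,
    interval: str,
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PsychometricFit:
    """Convenience wrapper: quartile-bin one participant's trials of one
    interval and run the fit + permutation test. Expects the metrics rows and
    trial rows of a single participant."""
    m = metrics[metrics["interval"] == interval].set_index("trial_index")
    tr = trials.set_index("trial_index")
    common = m.index.intersection(tr.index)
    lr = m.loc[common, "log_ratio"].to_numpy(dtype=float)
    right = (tr.loc[common, "button"] == "right").to_numpy()
    bins = quartile_bins(lr, right)
    return permutation_test_beta1(bins, n_shuffles=n_shuffles, seed=seed)
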