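"""Per-participant linear models linking gaze metrics to the four reported
cognitive indices (confidence C, reward R, interest I, complexity CM).

Two designs, fitted per participant and per interval with OLS:

* observation model: T (proportion of the interval spent looking at the
  selected option) on z-scored C, R, I, CM plus the interaction products
  R*I, R*CM, I*CM (products of z-scores; 8 coefficients);
* change-of-target models: the z-scored #CoT or fCoT metric on z-scored
  C, R, I, CM (5 coefficients).

Group-level inference is a one-sample t-test of each coefficient across
participants against zero (the two-stage summary-statistics approach).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .psychometrics import GroupTestResult, group_ttest

__all__ = [
    "GLMFit",
    "zscore",
    "fit_observation_glm",
    "fit_cot_glm",
    "group_coefficient_tests",
]

FACTORS = ["C", "R", "I", "CM"]
OBS_TERMS = ["const", "C", "R", "I", "CM", "RxI", "RxCM", "IxCM"]
COT_TERMS = ["const", "C", "R", "I", "CM"]


@dataclass(frozen=True)
class GLMFit:
    response_name: str
    interval: str
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    n_trials: int
    rank_deficient: bool = False


def zscore(values) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator; errors on zero variance."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _zscore_factors(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for f in FACTORS:
        try:
            out[f] = zscore(df[f])
        except ValueError as e:
            raise ValueError(f"factor {f}: {e}") from None
    return pd.DataFrame(out, index=df.index)


def _ols(X: np.ndarray, y: np.ndarray, terms: list[str], response: str,
         interval: str) -> GLMFit:
    rank = np.linalg.matrix_rank(X)
    model = sm.OLS(y, X).fit()
    return GLMFit(
        response_name=response,
        interval=interval,
        terms=tuple(terms),
        coefficients=np.asarray(model.params, dtype=float),
        standard_errors=np.asarray(model.bse, dtype=float),
        n_trials=int(len(y)),
        rank_deficient=rank < X.shape[1],
    )


def fit_observation_glm(data: pd.DataFrame, interval: str,
                        response: str = "t_selected_frac",
                        min_trials: int = 12) -> GLMFit:
    """Fit T = b0 + b1*C + b2*R + b3*I + b4*CM + b5*R*I + b6*R*CM + b7*I*CM
    for one participant on one interval.

    ``data`` holds one row per trial with the ratings and the interval's
    metrics already joined. The response is the raw proportion (not z-scored);
    interactions are products of z-scored main effects.
    """
    d = data.dropna(subset=[response] + FACTORS)
    if len(d) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {len(d)}")
    z = _zscore_factors(d)
    X = np.column_stack([
        np.ones(len(d)), z["C"], z["R"], z["I"], z["CM"],
        z["R"] * z["I"], z["R"] * z["CM"], z["I"] * z["CM"],
    ])
    return _ols(X, d[response].to_numpy(dtype=float), OBS_TERMS, response, interval)


def fit_cot_glm(data: pd.DataFrame, interval: str, metric: str = "n_cot",
                min_trials: int = 8) -> GLMFit:
    """Fit z(metric) = b0 + b1*C + b2*R + b3*I + b4*CM for one participant on
    one interval, where metric is n_cot or f_cot (z-scored response)."""
    if metric not in ("n_cot", "f_cot"):
        raise ValueError("metric must be 'n_cot' or 'f_cot'")
    d = data.dropna(subset=[metric] + FACTORS)
    if len(d) < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {len(d)}")
    z = _zscore_factors(d)
    y = zscore(d[metric])
    X = np.column_stack([np.ones(len(d)), z["C"], z["R"], z["I"], z["CM"]])
    return _ols(X, y, COT_TERMS, metric, interval)


def group_coefficient_tests(fits: list[GLMFit], with_bf: bool = False) -> pd.DataFrame:
    """One-sample t-test of every coefficient across participants against 0.

    Rank-deficient fits are dropped (reported in the 'n_dropped' attribute of
    no row; callers should log them). Returns one row per coefficient with the
    group mean, t, df, CI and p.
    """
    usable = [f for f in fits if not f.rank_deficient]
    if len(usable) < 2:
        raise ValueError("need at least 2 participants with valid fits")
    terms = usable[0].terms
    if any(f.terms != terms for f in usable):
        raise ValueError("fits mix different designs")
    rows = []
    for j, term in enumerate(terms):
        vals = np.array([f.coefficients[j] for f in usable])
        res: GroupTestResult = group_ttest(vals, mu0=0.0, with_bf=with_bf)
        rows.append({
            "coefficient": term,
            "response": usable[0].response_name,
            "interval": usable[0].interval,
            "mean": vals.mean(),
            "t_stat": res.t_stat,
            "df": res.df,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
            "n_participants": len(usable),
        })
    return pd.DataFrame(rows)
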