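"""End-to-end orchestration: simulate or load a dataset, reduce gaze to
metrics, run the psychometric, GLM and model-selection stages, and write the
summary artifacts (CSV tables, JSON scalars, a run manifest).

A single global seed expands into per-stage seeds through a fixed derivation
(numpy SeedSequence keyed by (seed, stage index)), so individual stages can be
re-run in isolation and reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import INTERVALS, MODEL_NAMES, EvidenceConfig, GenerativeConfig
from .gaze import exclude_trials, metrics_table
from .glm import fit_cot_glm, fit_observation_glm, group_coefficient_tests
from .model_selection import (attention_times, invert_participants, model_design,
                              posterior_coefficients, rfx_bms)
from .psychometrics import correlate_confidence_dt, fit_participant_interval, group_ttest
from .simulate import simulate_dataset

__all__ = [
    "stage_seed",
    "analyze_dataset",
    "confidence_dt_quartile_summary",
    "run_pipeline",
]

_STAGES = {"simulate": 0, "psychometrics": 1, "bms": 2, "recover": 3, "quartiles": 4}


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed sequence derived from the global seed."""
    return np.random.SeedSequence(entropy=(int(seed), _STAGES[stage]))


def _psychometric_stage(metrics: pd.DataFrame, trials: pd.DataFrame,
                        seed: int, n_shuffles: int = 10_000,
                        intervals: tuple[str, ...] = ("SOn", "SOffUD")) -> tuple[pd.DataFrame, dict]:
    rows = []
    pids = sorted(trials["participant_id"].unique())
    children = stage_seed(seed, "psychometrics").spawn(len(pids) * len(intervals))
    i = 0
    for pid in pids:
        m = metrics[metrics["participant_id"] == pid]
        tr = trials[trials["participant_id"] == pid]
        for iv in intervals:
            ss = children[i]
            i += 1
            try:
                fit = fit_participant_interval(m, tr, iv, n_shuffles,
                                               np.random.default_rng(ss))
            except ValueError:
                continue  # too few trials for quartiles
            rows.append({"participant_id": pid, "interval": iv,
                         "beta0": fit.beta0, "beta1": fit.beta1,
                         "perm_p": fit.perm_p, "significant": fit.significant})
    fits = pd.DataFrame(rows)
    group = {}
    for iv in intervals:
        vals = fits.loc[fits["interval"] == iv, "beta1"]
        if len(vals) >= 2 and vals.std(ddof=1) > 0:
            group[iv] = dataclasses.asdict(group_ttest(vals.to_numpy(), mu0=0.0))
    return fits, group


def _glm_stage(metrics: pd.DataFrame, trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    coef_rows, group_frames = [], []
    merged = metrics.merge(trials, on=["participant_id", "trial_index"])
    specs = [("t_selected_frac", fit_observation_glm, {}),
             ("n_cot", fit_cot_glm, {"metric": "n_cot"}),
             ("f_cot", fit_cot_glm, {"metric": "f_cot"})]
    for response, fitter, kw in specs:
        for iv in INTERVALS:
            fits = []
            for pid, grp in merged[merged["interval"] == iv].groupby("participant_id"):
                try:
                    fit = fitter(grp, iv, **kw)
                except (ValueError, KeyError):
                    continue
                fits.append(fit)
                for term, est, se in zip(fit.terms, fit.coefficients, fit.standard_errors):
                    coef_rows.append({"participant_id": pid, "response": response,
                                      "interval": iv, "coefficient": term,
                                      "estimate": est, "se": se, "n_trials": fit.n_trials})
            if len([f for f in fits if not f.rank_deficient]) >= 2:
                group_frames.append(group_coefficient_tests(fits))
    coefs = pd.DataFrame(coef_rows)
    groups = pd.concat(group_frames, ignore_index=True) if group_frames else pd.DataFrame()
    return coefs, groups


def confidence_dt_quartile_summary(
    trials: pd.DataFrame,
    att: pd.DataFrame,
    model_alphas: Optional[dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Reported-confidence quartiles vs decision time, with per-model
    predicted confidence.

    Per participant, valid trials are ranked by the confidence rating and cut
    into four equal-count quartiles (participants with fewer than 4 distinct
    confidence values are skipped); quartile-wise decision-time means and
    standard errors are pooled across participants. When fitted model
    coefficients are supplied (model name -> alpha vector in design-column
    order), the mean predicted confidence per quartile is attached.
    """
    d = trials.merge(att, on=["participant_id", "trial_index"], how="inner")
    d = d[d["decision_time_ms"].notna()]
    parts = []
    for pid, grp in d.groupby("participant_id"):
        if grp["C"].nunique() < 4:
            continue
        order = np.argsort(grp["C"].to_numpy(), kind="stable")
        n = len(grp)
        q = np.empty(n, dtype=int)
        sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
        start = 0
        for qi, sz in enumerate(sizes):
            q[order[start:start + sz]] = qi
            start += sz
        parts.append(grp.assign(quartile=q))
    if not parts:
        raise ValueError("no participant has 4 distinct confidence values")
    pooled = pd.concat(parts, ignore_index=True)

    preds = {}
    if model_alphas:
        dt1, dt2 = pooled["dt1_s"].to_numpy(), pooled["dt2_s"].to_numpy()
        for name, alpha in model_alphas.items():
            cols = {"const": np.ones(len(pooled)), "dt_diff_s": dt1 - dt2,
                    "inv_total_s": 1.0 / (dt1 + dt2)}
            from .model_selection import DESIGN_COLUMNS
            X = np.column_stack([cols[c] for c in DESIGN_COLUMNS[name]])
            preds[f"pred_{name}"] = X @ np.asarray(alpha)
    for k, v in preds.items():
        pooled[k] = v

    rows = []
    for qi, grp in pooled.groupby("quartile"):
        dt = grp["decision_time_ms"].to_numpy()
        row = {"quartile": int(qi),
               "confidence_mean": grp["C"].mean(),
               "dt_mean_ms": dt.mean(),
               "dt_se_ms": dt.std(ddof=1) / np.sqrt(len(dt)),
               "n_trials": len(dt)}
        for k in preds:
            row[k] = grp[k].mean()
        rows.append(row)
    return pd.DataFrame(rows).sort_values("quartile").reset_index(drop=True)


def analyze_dataset(
    gaze: pd.DataFrame,
    trials: pd.DataFrame,
    cfg: GenerativeConfig | None = None,
    evidence_cfg: EvidenceConfig = EvidenceConfig(),
    seed: int = 0,
    n_shuffles: int = 10_000,
    n_dirichlet_samples: int = 1_000_000,
) -> dict:
    """Run every analysis stage on one dataset; returns a dict of tables and
    scalar results. ``cfg`` supplies geometry and the rating scale (defaults
    are used when absent)."""
    cfg = cfg or GenerativeConfig()
    kept, exclusion_report = exclude_trials(trials)
    metrics = metrics_table(gaze, kept, cfg.geometry)

    psycho_fits, psycho_group = _psychometric_stage(metrics, kept, seed, n_shuffles)
    glm_coefs, glm_groups = _glm_stage(metrics, kept)
    corr_table, corr_group = correlate_confidence_dt(kept)

    att = attention_times(metrics, kept)
    F = invert_participants(att, kept, evidence_cfg, cfg.rating_scale_max)
    bms_seed = int(stage_seed(seed, "bms").generate_state(1)[0] % (2**31))
    bms = rfx_bms(F, n_dirichlet_samples=n_dirichlet_samples, seed=bms_seed)

    # group-average fitted coefficients per model, for the quartile overlay
    data = att.merge(kept[["participant_id", "trial_index", "C"]],
                     on=["participant_id", "trial_index"])
    model_alphas = {}
    for name in MODEL_NAMES:
        means = []
        for _, grp in data.groupby("participant_id"):
            X, y = model_design(grp, name, cfg.rating_scale_max)
            if len(y) > X.shape[1]:
                means.append(posterior_coefficients(X, y, evidence_cfg)[0])
        if means:
            model_alphas[name] = np.mean(means, axis=0)
    quartiles = confidence_dt_quartile_summary(kept, att, model_alphas)

    return {
        "kept_trials": kept,
        "exclusion_report": exclusion_report,
        "metrics": metrics,
        "psychometric_fits": psycho_fits,
        "psychometric_group": psycho_group,
        "glm_coefficients": glm_coefs,
        "glm_group_tests": glm_groups,
        "confidence_dt_correlations": corr_table,
        "confidence_dt_group": dataclasses.asdict(corr_group),
        "free_energy": F,
        "bms": bms,
        "model_alphas": {k: v.tolist() for k, v in model_alphas.items()},
        "quartile_summary": quartiles,
    }


def _write_outputs(result: dict, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out / name, index=index)
        written.append(name)

    _csv(result["metrics"], "metrics.csv")
    _csv(result["exclusion_report"], "exclusions.csv")
    _csv(result["psychometric_fits"], "psychometric_fits.csv")
    _csv(result["glm_coefficients"], "glm_coefficients.csv")
    if len(result["glm_group_tests"]):
        _csv(result["glm_group_tests"], "glm_group_tests.csv")
    _csv(result["confidence_dt_correlations"], "confidence_dt_correlations.csv")
    _csv(result["free_energy"], "free_energy.csv", index=True)
    _csv(result["quartile_summary"], "quartile_summary.csv")

    bms = result["bms"]
    scalars = {
        "psychometric_group": result["psychometric_group"],
        "confidence_dt_group": result["confidence_dt_group"],
        "model_alphas": result["model_alphas"],
        "bms": {
            "model_names": list(bms.model_names),
            "dirichlet_alpha": bms.dirichlet_alpha.tolist(),
            "model_frequency": bms.model_frequency.tolist(),
            "exceedance_prob": bms.exceedance_prob.tolist(),
            "n_dirichlet_samples": bms.n_dirichlet_samples,
            "seed": bms.seed,
        },
    }
    (out / "results.json").write_text(json.dumps(scalars, indent=2, default=float))
    written.append("results.json")
    return written


def run_pipeline(
    cfg: GenerativeConfig,
    mode: str,
    out_dir: str | Path,
    evidence_cfg: EvidenceConfig = EvidenceConfig(),
    seed: Optional[int] = None,
    n_shuffles: int = 10_000,
    n_dirichlet_samples: int = 1_000_000,
) -> dict:
    """Run one pipeline mode and write its artifacts under ``out_dir``.

    simulate: write the synthetic gaze/trial/truth CSVs.
    analyze:  simulate in memory, run every stage, write tables + results.json.
    recover:  run the 3x3 model-recovery confusion table.
    Every run writes a manifest (config echo, seed, outputs).
    """
    if mode not in ("simulate", "analyze", "recover"):
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    written: list[str] = []

    if mode == "simulate":
        gaze, trials, truth = simulate_dataset(cfg)
        gaze.to_csv(out / "gaze.csv", index=False)
        trials.to_csv(out / "trials.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        written = ["gaze.csv", "trials.csv", "truth.csv"]
        result = {"gaze": gaze, "trials": trials, "truth": truth}
    elif mode == "analyze":
        gaze, trials, _ = simulate_dataset(cfg)
        result = analyze_dataset(gaze, trials, cfg, evidence_cfg, seed,
                                 n_shuffles, n_dirichlet_samples)
        written = _write_outputs(result, out)
    else:
        from .model_selection import model_recovery
        table = model_recovery(cfg, evidence_cfg, seed=seed)
        table.to_csv(out / "recovery_confusion.csv", index=False)
        written = ["recovery_confusion.csv"]
        result = {"recovery": table}

    manifest = {
        "mode": mode,
        "seed": int(seed),
        "config": dataclasses.asdict(cfg),
        "evidence_config": dataclasses.asdict(evidence_cfg),
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
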