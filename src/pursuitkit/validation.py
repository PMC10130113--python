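"""Simulation studies validating the full pipeline.

These studies close the loop between the simulator and the analysis
layer: cohorts are generated with known ground truth, pushed through
scoring and model fitting, and the recovered quantities are compared
with the generative values.

* :func:`coverage_study` — does the random-intercept LMM recover the
  true score-model weights, with confidence intervals that cover the
  truth at (roughly) their nominal level?
* :func:`dominance_study` — do the qualitative patterns hold: the
  directional offsets (which generate the score) dominate the score's
  part R2 across trajectories, while age relates more strongly to the
  spatial offsets (which the generator ages through visuomotor lag)?
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from pursuitkit.analysis import fit_lmm, run_paper_analysis
from pursuitkit.simulator import SCORE_LABELS, CohortSpec, simulate_cohort
from pursuitkit.stimulus import build_battery

PRIMARY = [f"dir_{lab}" for lab in SCORE_LABELS]


def coverage_study(
    n_replicates: int = 200,
    seed: int = 0,
    spec: CohortSpec | None = None,
    ci_level: float = 0.95,
) -> dict:
    """CI coverage of the LMM score-model weight estimates.

    Each replicate simulates a fresh cohort at the default design (12
    participants, 4 sessions), fits the random-intercept LMM of the
    external score on the two primary directional offsets, and checks
    whether the Satterthwaite-t confidence interval covers the true
    generative weight.
    """
    spec = spec or CohortSpec()
    battery = build_battery()
    score_battery = {lab: battery[lab] for lab in SCORE_LABELS}
    true = {
        "dir_spiralA": spec.score_weight_spiralA,
        "dir_zigzagA": spec.score_weight_zigzagA,
    }
    hits = {k: 0 for k in true}
    n_ok = 0
    for rep in range(n_replicates):
        rep_spec = dataclasses.replace(spec, seed=(seed * 100003 + rep) % 2**31)
        cohort, _ = simulate_cohort(
            rep_spec, battery=score_battery, labels=list(SCORE_LABELS)
        )
        m = fit_lmm(cohort, PRIMARY)
        n_ok += 1
        for name, truth in true.items():
            se = m.se[name]
            ddf = m.f_tests[name]["df_den"]
            tcrit = stats.t.ppf(0.5 + ci_level / 2, ddf)
            est = m.coefficients[name]
            if est - tcrit * se <= truth <= est + tcrit * se:
                hits[name] += 1
    per_weight = {k: v / n_ok for k, v in hits.items()}
    return {
        "n_replicates": n_ok,
        "coverage": per_weight,
        "coverage_overall": float(np.mean(list(per_weight.values()))),
        "ci_level": ci_level,
    }


def dominance_study(
    n_replicates: int = 100,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> dict:
    """Qualitative metric-dominance patterns over replicated cohorts.

    For each replicate (full nine-trajectory battery) the analysis
    report is computed and two counts are taken over the nine
    trajectories: on how many does the *directional* offset carry more
    marginal part R2 for the score than the spatial offset, and on how
    many does age explain more marginal R2 of the *spatial* offset than
    of the directional one.  Medians over replicates are returned.
    """
    spec = spec or CohortSpec()
    battery = build_battery()
    rq2_counts, rq3_counts, r2m_values = [], [], []
    for rep in range(n_replicates):
        rep_spec = dataclasses.replace(spec, seed=(seed * 99991 + rep) % 2**31)
        cohort, _ = simulate_cohort(rep_spec, battery=battery)
        report = run_paper_analysis(cohort)
        labels = sorted({k[4:] for k in report["rq3"]})
        rq2_counts.append(
            sum(
                report["rq2"][f"dir_{lab}"]["part_r2_marginal"]
                > report["rq2"][f"spa_{lab}"]["part_r2_marginal"]
                for lab in labels
                if f"dir_{lab}" in report["rq2"] and f"spa_{lab}" in report["rq2"]
            )
        )
        rq3_counts.append(
            sum(
                report["rq3"][f"spa_{lab}"]["marginal_r2"]
                > report["rq3"][f"dir_{lab}"]["marginal_r2"]
                for lab in labels
            )
        )
        r2m_values.append(report["rq1_repeated"]["marginal_r2"])
    return {
        "n_replicates": n_replicates,
        "n_trajectories": 9,
        "rq2_directional_dominates_median": float(np.median(rq2_counts)),
        "rq3_spatial_dominates_median": float(np.median(rq3_counts)),
        "score_model_marginal_r2_median": float(np.median(r2m_values)),
    }
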