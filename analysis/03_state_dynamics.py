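"""Temporal dynamics of the extracted brain states, drug vs placebo.

Computes fractional occupancy, dwell time, appearance rate and transition
probabilities per subject and condition from the state labels of step 02,
then paired two-sided t-tests with Benjamini-Hochberg correction within
each metric family.  Writes per-subject metrics and the contrast table.
"""

import numpy as np
import pandas as pd
from _common import DATA, K, RESULTS, ensure_dirs, require

from brainctl import io as bio
from brainctl.dynamics import StateSequence, summarize
from brainctl.stats import bh_correct, paired_ttest

ensure_dirs()
cohort = bio.read_cohort(require(DATA / "cohort" / "manifest.json", "01_simulate_cohort.py"))
labels = pd.read_csv(require(RESULTS / "02_state_labels.tsv", "02_extract_states.py"), sep="\t")

by_subject = {}
for scan in cohort.scans:
    lab = labels.loc[labels.scan_id == scan.scan_id, "state"].to_numpy()
    seq = StateSequence(
        scans=(lab,), tr_seconds=scan.tr_seconds,
        subject_id=scan.subject_id, condition=scan.condition,
    )
    by_subject.setdefault(scan.subject_id, {})[scan.condition] = summarize(seq, K)

rows = []
for sid, conds in by_subject.items():
    for cond, s in conds.items():
        for j in range(K):
            rows.append(
                dict(
                    subject=sid, condition=cond, state=j + 1,
                    fractional_occupancy=s.fractional_occupancy[j],
                    dwell_time_seconds=s.dwell_time_seconds[j],
                    appearance_rate_per_min=s.appearance_rate_per_min[j],
                    persistence_probability=s.transition_probabilities[j, j],
                )
            )
metrics = pd.DataFrame(rows)
metrics.to_csv(RESULTS / "03_dynamics_per_subject.csv", index=False)

contrast_rows = []
for metric in ("fractional_occupancy", "dwell_time_seconds",
               "appearance_rate_per_min", "persistence_probability"):
    pvals, recs = [], []
    for j in range(1, K + 1):
        sub = metrics[metrics.state == j].pivot(
            index="subject", columns="condition", values=metric
        )
        t, p = paired_ttest(sub["drug"], sub["placebo"])
        pvals.append(p)
        recs.append(
            dict(metric=metric, state=j, mean_drug=sub["drug"].mean(),
                 mean_placebo=sub["placebo"].mean(), t=t, p=p)
        )
    for rec, q in zip(recs, bh_correct(pvals)):
        rec["p_adj"] = q
        contrast_rows.append(rec)
contrast = pd.DataFrame(contrast_rows)
contrast.to_csv(RESULTS / "03_dynamics_contrast.csv", index=False)

sig = contrast[contrast.p_adj < 0.05]
print(f"{len(sig)}/{len(contrast)} state-metric contrasts significant after BH")
print(contrast.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
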