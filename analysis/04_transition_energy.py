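"""Minimum transition energies between brain states, drug vs placebo.

Normalises the structural connectome into a stable linear system, computes
each subject-condition's individual state centroids, and evaluates the full
k x k minimum-control-energy matrix under uniform control input.  Paired
t-tests with BH across the 16 ordered pairs test whether the drug condition's
energy landscape is flattened (all transitions cheaper).
"""

import numpy as np
import pandas as pd
from _common import DATA, K, RESULTS, SEED, T_HORIZON, ensure_dirs, require

from brainctl import io as bio
from brainctl.energy import build_control_matrix, normalize_connectome, transition_energy_matrix
from brainctl.states import Partition, compute_centroids
from brainctl.stats import bh_correct, paired_ttest

ensure_dirs()
cohort = bio.read_cohort(require(DATA / "cohort" / "manifest.json", "01_simulate_cohort.py"))
labels = pd.read_csv(require(RESULTS / "02_state_labels.tsv", "02_extract_states.py"), sep="\t")
A = bio.read_matrix_tsv(DATA / "connectome.tsv").to_numpy()

system = normalize_connectome(A)
B = build_control_matrix(n_regions=system.n_regions).B
print(f"connectome spectral radius {system.spectral_radius:.2f}; "
      f"stability margin {system.stability_margin:.4f}")

# rebuild a Partition shell so compute_centroids can slice per scan
slices, all_labels, start = {}, [], 0
for scan in cohort.scans:
    lab = labels.loc[labels.scan_id == scan.scan_id, "state"].to_numpy()
    slices[scan.scan_id] = slice(start, start + len(lab))
    all_labels.append(lab)
    start += len(lab)
all_labels = np.concatenate(all_labels)
centroid_table = bio.read_matrix_tsv(RESULTS / "02_group_centroids.tsv").to_numpy()
partition = Partition(
    labels=all_labels, centroids=centroid_table, k=K, variance_explained=np.nan,
    seed=SEED, inertia=np.nan, scan_slices=slices,
)

te_records = {}
for scan in cohort.scans:
    ind = compute_centroids(
        cohort.scans, partition, level="subject-condition",
        subject_id=scan.subject_id, condition=scan.condition,
    )
    C = np.nan_to_num(ind.centroids, nan=0.0)
    te = transition_energy_matrix(system.A_norm, B, C, T_HORIZON, missing=ind.missing)
    te_records[(scan.subject_id, scan.condition)] = te.E

rows = []
for (sid, cond), E in te_records.items():
    for i in range(K):
        for j in range(K):
            rows.append(dict(subject=sid, condition=cond, from_state=i + 1,
                             to_state=j + 1, energy=E[i, j]))
per_subject = pd.DataFrame(rows)
per_subject.to_csv(RESULTS / "04_transition_energy_per_subject.csv", index=False)

contrast_rows, pvals = [], []
for i in range(1, K + 1):
    for j in range(1, K + 1):
        sub = per_subject[(per_subject.from_state == i) & (per_subject.to_state == j)]
        piv = sub.pivot(index="subject", columns="condition", values="energy")
        t, p = paired_ttest(piv["drug"], piv["placebo"])
        pvals.append(p)
        contrast_rows.append(
            dict(from_state=i, to_state=j, mean_drug=piv["drug"].mean(),
                 mean_placebo=piv["placebo"].mean(), t=t, p=p)
        )
for rec, q in zip(contrast_rows, bh_correct(pvals)):
    rec["p_adj"] = q
contrast = pd.DataFrame(contrast_rows)
contrast.to_csv(RESULTS / "04_transition_energy_contrast.csv", index=False)

lower = (contrast.mean_drug < contrast.mean_placebo).sum()
sig = (contrast.p_adj < 0.05).sum()
print(f"drug energy lower for {lower}/{K * K} transitions "
      f"({sig} significant after BH) — flattened energy landscape"
      if lower == K * K else
      f"drug energy lower for {lower}/{K * K} transitions ({sig} significant)")
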