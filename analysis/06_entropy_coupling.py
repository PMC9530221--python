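"""Entropy of meta-state sequences and its coupling to energy flattening.

Binarises each subject-condition state sequence to meta-states, computes
normalised Lempel-Ziv complexity, contrasts conditions, and relates each
subject's relative transition-energy change to their relative changes in
dwell time, appearance rate and entropy via partial correlations that
control for mean framewise displacement.
"""

import numpy as np
import pandas as pd
from _common import DATA, K, RESULTS, ensure_dirs, require

from brainctl import io as bio
from brainctl.complexity import normalized_lz
from brainctl.dynamics import StateSequence, binarize_to_meta_states, summarize
from brainctl.states import pair_meta_states
from brainctl.stats import paired_ttest, partial_correlation, relative_difference

ensure_dirs()
cohort = bio.read_cohort(require(DATA / "cohort" / "manifest.json", "01_simulate_cohort.py"))
labels = pd.read_csv(require(RESULTS / "02_state_labels.tsv", "02_extract_states.py"), sep="\t")
centroids = bio.read_matrix_tsv(
    require(RESULTS / "02_group_centroids.tsv", "02_extract_states.py")
).to_numpy()
te = pd.read_csv(
    require(RESULTS / "04_transition_energy_per_subject.csv", "04_transition_energy.py")
)

meta_assignment, _, _ = pair_meta_states(centroids)

records = []
for scan in cohort.scans:
    lab = labels.loc[labels.scan_id == scan.scan_id, "state"].to_numpy()
    seq = StateSequence(scans=(lab,), tr_seconds=scan.tr_seconds,
                        subject_id=scan.subject_id, condition=scan.condition)
    bits = binarize_to_meta_states(seq, meta_assignment)
    s = summarize(seq, K)
    records.append(
        dict(subject=scan.subject_id, condition=scan.condition,
             normalized_lz=normalized_lz(bits),
             mean_dwell=np.nanmean(s.dwell_time_seconds),
             mean_appearance=np.nanmean(s.appearance_rate_per_min))
    )
df = pd.DataFrame(records)
df.to_csv(RESULTS / "06_entropy_per_subject.csv", index=False)

piv = df.pivot(index="subject", columns="condition", values="normalized_lz")
t, p = paired_ttest(piv["drug"], piv["placebo"])
print(f"normalized LZ: drug {piv['drug'].mean():.4f} vs placebo "
      f"{piv['placebo'].mean():.4f} (t = {t:.2f}, p = {p:.3f})")

mean_te = te.groupby(["subject", "condition"]).energy.mean().unstack()
rel_te = relative_difference(mean_te["drug"].to_numpy(), mean_te["placebo"].to_numpy())
fd = np.array([cohort.mean_fd[s] for s in mean_te.index])

rows = []
for metric in ("mean_dwell", "mean_appearance", "normalized_lz"):
    pv = df.pivot(index="subject", columns="condition", values=metric).loc[mean_te.index]
    rel = relative_difference(pv["drug"].to_numpy(), pv["placebo"].to_numpy())
    r, pval = partial_correlation(rel_te, rel, fd)
    rows.append(dict(metric=metric, partial_r=r, p=pval, n=len(rel)))
    print(f"relative TE change vs relative {metric} change: "
          f"partial r = {r:+.3f} (p = {pval:.3f}, controlling mean FD)")
pd.DataFrame(rows).to_csv(RESULTS / "06_energy_behaviour_correlations.csv", index=False)
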