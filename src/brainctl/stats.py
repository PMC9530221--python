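"""Group-level statistics: paired tests, FDR correction, relative differences,
and motion-controlled partial correlations.

Paired contrasts (drug vs placebo within subject) use the classical two-sided
paired t-test; families of p-values are corrected with Benjamini-Hochberg,
scoped per metric family (each dynamics metric across its k states; the k*k
transition-energy entries as one family).  Per-subject effect sizes are
expressed as the relative difference (a - b)/(a + b), and brain-behaviour
associations are Pearson correlations of residuals after regressing out the
subject's mean framewise displacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "paired_ttest",
    "bh_correct",
    "relative_difference",
    "partial_correlation",
    "group_report",
]


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; pairs with any NaN are dropped (count logged).

    Returns ``(t, p)`` with ``df = n - 1``.  Raises if fewer than 3 complete
    pairs remain or the differences have zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ValueError("differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def bh_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def relative_difference(a, b):
    """(a - b) / (a + b): in [-1, 1] for nonnegative inputs; errors when a+b=0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    if np.any(denom == 0):
        raise ZeroDivisionError("relative difference undefined where a + b = 0")
    out = (a - b) / denom
    return float(out) if out.ndim == 0 else out


def partial_correlation(x, y, covariate) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out a covariate.

    Both variables are residualised on ``[1, covariate]`` by least squares;
    the two-sided p-value uses the t-approximation with ``n - 3`` degrees of
    freedom.  With a constant covariate this reduces exactly to the plain
    Pearson correlation (the regression then only removes the mean).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(x)
    if len(y) != n or len(c) != n:
        raise ValueError("x, y and covariate must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("residuals are constant; partial correlation undefined")
    r = float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 3
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def group_report(
    dynamics_by_subject: dict,
    te_by_subject: dict,
    entropy_by_subject: dict | None = None,
    mean_fd: dict | None = None,
    conditions: tuple = ("drug", "placebo"),
) -> dict:
    """Assemble tidy paired-contrast tables across a two-condition cohort.

    Parameters
    ----------
    dynamics_by_subject
        ``{subject_id: {condition: DynamicsSummary}}``.
    te_by_subject
        ``{subject_id: {condition: TransitionEnergyMatrix}}``.
    entropy_by_subject
        Optional ``{subject_id: {condition: float}}`` normalised LZ values.
    mean_fd
        Optional ``{subject_id: float}`` motion covariate for the
        partial-correlation table.

    Returns a dict of DataFrames: ``"dynamics"`` (per metric x state paired t
    with BH within each metric family), ``"transition_energy"`` (per ordered
    pair, BH across all k*k entries), ``"entropy"`` and
    ``"brain_behaviour"`` (per-subject relative TE change vs relative
    dwell/appearance/entropy change, partially correlated controlling FD).
    """
    cond_a, cond_b = conditions
    subjects = sorted(set(dynamics_by_subject) & set(te_by_subject))
    if not subjects:
        raise ValueError("no subjects with both dynamics and energy records")
    k = len(next(iter(dynamics_by_subject.values()))[cond_a].fractional_occupancy)

    rows = []
    metric_getters = {
        "fractional_occupancy": lambda s: s.fractional_occupancy,
        "dwell_time_seconds": lambda s: s.dwell_time_seconds,
        "appearance_rate_per_min": lambda s: s.appearance_rate_per_min,
    }
    for metric, get in metric_getters.items():
        pvals, recs = [], []
        for state in range(k):
            va = np.array([get(dynamics_by_subject[s][cond_a])[state] for s in subjects])
            vb = np.array([get(dynamics_by_subject[s][cond_b])[state] for s in subjects])
            t, p = paired_ttest(va, vb)
            pvals.append(p)
            recs.append(
                dict(metric=metric, state=state + 1, mean_a=np.nanmean(va),
                     mean_b=np.nanmean(vb), t=t, p=p)
            )
        padj = bh_correct(pvals)
        for rec, q in zip(recs, padj):
            rec["p_adj"] = q
            rows.append(rec)
    dynamics_table = pd.DataFrame(rows)

    te_rows, pvals = [], []
    for i in range(k):
        for j in range(k):
            va = np.array([te_by_subject[s][cond_a].E[i, j] for s in subjects])
            vb = np.array([te_by_subject[s][cond_b].E[i, j] for s in subjects])
            t, p = paired_ttest(va, vb)
            pvals.append(p)
            te_rows.append(
                dict(from_state=i + 1, to_state=j + 1, mean_a=np.nanmean(va),
                     mean_b=np.nanmean(vb), t=t, p=p)
            )
    for rec, q in zip(te_rows, bh_correct(pvals)):
        rec["p_adj"] = q
    te_table = pd.DataFrame(te_rows)

    entropy_table = None
    if entropy_by_subject:
        ea = np.array([entropy_by_subject[s][cond_a] for s in subjects])
        eb = np.array([entropy_by_subject[s][cond_b] for s in subjects])
        t, p = paired_ttest(ea, eb)
        entropy_table = pd.DataFrame(
            [dict(metric="normalized_lz", mean_a=ea.mean(), mean_b=eb.mean(), t=t, p=p)]
        )

    behaviour_table = None
    if mean_fd is not None:
        fd = np.array([mean_fd[s] for s in subjects])
        te_a = np.array([np.nanmean(te_by_subject[s][cond_a].E) for s in subjects])
        te_b = np.array([np.nanmean(te_by_subject[s][cond_b].E) for s in subjects])
        rel_te = relative_difference(te_a, te_b)
        brows = []
        targets = {
            "dwell_time_seconds": lambda s, c: np.nanmean(
                dynamics_by_subject[s][c].dwell_time_seconds
            ),
            "appearance_rate_per_min": lambda s, c: np.nanmean(
                dynamics_by_subject[s][c].appearance_rate_per_min
            ),
        }
        if entropy_by_subject:
            targets["normalized_lz"] = lambda s, c: entropy_by_subject[s][c]
        for name, get in targets.items():
            va = np.array([get(s, cond_a) for s in subjects])
            vb = np.array([get(s, cond_b) for s in subjects])
            rel = relative_difference(va, vb)
            r, p = partial_correlation(rel_te, rel, fd)
            brows.append(dict(metric=name, r=r, p=p, n=len(subjects)))
        behaviour_table = pd.DataFrame(brows)

    return {
        "dynamics": dynamics_table,
        "transition_energy": te_table,
        "entropy": entropy_table,
        "brain_behaviour": behaviour_table,
    }
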