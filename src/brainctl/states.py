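"""Extraction and characterisation of recurrent brain states.

Brain states are cluster centroids of parcellated BOLD frames pooled across
all scans.  Clustering is Lloyd-style k-means with correlation distance
(1 - Pearson r between a frame and a centroid, computed across regions),
restarted from many random initialisations and the best solution kept;
stability across independent repetitions is assessed with adjusted mutual
information (AMI), and the partition sharing the greatest total AMI with all
others is retained.  Centroids split into anti-correlated sub-state pairs
("meta-states"), and each centroid's supra-/sub-mean activity is compared to
binary resting-state-network masks by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_mutual_info_score

__all__ = [
    "Partition",
    "BrainStateSet",
    "cluster_states",
    "select_partition_by_ami",
    "variance_explained",
    "elbow_scan",
    "compute_centroids",
    "rsn_alignment",
    "pair_meta_states",
    "match_states",
    "concat_scans",
]


@dataclass
class Partition:
    """A k-means partition of all pooled frames.

    ``labels`` are 1..k over the concatenated frames; ``scan_slices`` maps
    each scan id to its slice of the concatenation.
    """

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    variance_explained: float
    seed: int
    inertia: float  # sum of within-cluster correlation distances
    scan_slices: dict = field(default_factory=dict)

    def labels_for(self, scan_id: str) -> np.ndarray:
        sl = self.scan_slices[scan_id]
        return self.labels[sl]


@dataclass
class BrainStateSet:
    """Named centroids with optional meta-state pairing and missing flags."""

    centroids: np.ndarray
    level: str  # group | condition | subject-condition
    names: list
    meta_assignment: dict | None = None  # sub-state (1..k) -> meta-state (0..)
    missing: np.ndarray | None = None  # boolean per state
    pair_correlations: list | None = None


def concat_scans(scans) -> tuple[np.ndarray, dict]:
    """Concatenate scan matrices in order; return frames x regions and slices."""
    if not scans:
        raise ValueError("no scans supplied")
    n_regions = scans[0].n_regions
    mats, slices, start = [], {}, 0
    for scan in scans:
        if scan.n_regions != n_regions:
            raise ValueError("all scans must share the same region set")
        mats.append(scan.values)
        slices[scan.scan_id] = slice(start, start + scan.n_frames)
        start += scan.n_frames
    return np.vstack(mats), slices


def _row_standardize(X: np.ndarray) -> np.ndarray:
    """Standardise rows (zero mean, unit norm across regions) for Pearson r."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    ok = norms.squeeze(-1) > 0
    Xs = np.zeros_like(Xc)
    Xs[ok] = Xc[ok] / norms[ok]
    return Xs


def _corr_dist(frames_std: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson r between each standardized frame and each centroid."""
    return 1.0 - frames_std @ _row_standardize(centroids).T


def _lloyd_correlation(X, Xs, k, rng, max_iter=300):
    """One k-means run: correlation-distance assignment, mean-update centroids.

    Frames with zero variance across regions (all-constant rows) fall back to
    Euclidean distance for assignment.  Empty clusters are reseeded from the
    frame farthest from its centroid.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    degenerate = np.linalg.norm(Xs, axis=1) == 0
    for _ in range(max_iter):
        D = _corr_dist(Xs, centroids)
        if degenerate.any():
            # constant frames: correlation undefined; use Euclidean distance
            diffs = X[degenerate, None, :] - centroids[None, :, :]
            D[degenerate] = np.linalg.norm(diffs, axis=2)
        new_labels = D.argmin(axis=1)
        for j in range(k):
            if not np.any(new_labels == j):  # reseed empty cluster
                worst = int(np.argmax(D[np.arange(n), new_labels]))
                new_labels[worst] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    inertia = float(_corr_dist(Xs, centroids)[np.arange(n), labels].sum())
    return labels, centroids, inertia


def cluster_states(scans, k: int = 4, n_replicates: int = 50, seed: int = 0) -> Partition:
    """Cluster pooled frames into k states; best of ``n_replicates`` restarts.

    Distance is 1 - Pearson r between frame and centroid; the replicate with
    the smallest within-cluster distance sum wins; final centroids are plain
    means of member frames.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    X, slices = concat_scans(scans)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available frames")
    Xs = _row_standardize(X)
    best = None
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        labels, centroids, inertia = _lloyd_correlation(X, Xs, k, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    ve = _variance_explained_arrays(X, labels, centroids)
    return Partition(
        labels=labels + 1,
        centroids=centroids,
        k=k,
        variance_explained=ve,
        seed=seed,
        inertia=inertia,
        scan_slices=slices,
    )


def _variance_explained_arrays(X, labels0, centroids) -> float:
    within = float(((X - centroids[labels0]) ** 2).sum())
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 1.0
    return 1.0 - within / total


def variance_explained(partition: Partition, scans) -> float:
    """Fraction of total variance captured by the cluster centroids.

    ``1 - within-cluster SS / total SS about the grand mean``; equals the
    stored value but recomputed from the data for auditability.
    """
    X, _ = concat_scans(scans)
    if len(partition.labels) != X.shape[0]:
        raise ValueError("partition labels do not align with the supplied frames")
    return _variance_explained_arrays(X, partition.labels - 1, partition.centroids)


def select_partition_by_ami(partitions) -> Partition:
    """Pick the partition with the greatest summed AMI to all others.

    AMI is label-permutation invariant, so consistently re-labelled replicates
    agree perfectly.  Ties break to the lowest index.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions to compare")
    n = len(partitions[0].labels)
    for p in partitions:
        if len(p.labels) != n:
            raise ValueError("partitions cover different numbers of frames")
    m = len(partitions)
    totals = np.zeros(m)
    for i in range(m):
        for j in range(i + 1, m):
            a = adjusted_mutual_info_score(partitions[i].labels, partitions[j].labels)
            totals[i] += a
            totals[j] += a
    return partitions[int(np.argmax(totals))]


def elbow_scan(scans, k_range=range(2, 15), n_replicates: int = 10, seed: int = 0,
               gain_threshold: float = 0.01):
    """Variance explained for each k, and the first k whose gain to k+1 < 1%.

    Returns ``(table, k_elbow)`` where ``table`` is a list of
    ``(k, variance_explained)`` and ``k_elbow`` is the smallest k whose
    increment to k+1 falls below ``gain_threshold`` (None if none does).
    The scan is advisory: nothing downstream consumes its choice.
    """
    ks = list(k_range)
    if ks != list(range(ks[0], ks[-1] + 1)) or ks[0] < 2:
        raise ValueError("k_range must be contiguous with minimum >= 2")
    ve = [cluster_states(scans, k=k, n_replicates=n_replicates, seed=seed).variance_explained
          for k in ks]
    k_elbow = None
    for i in range(len(ks) - 1):
        if ve[i + 1] - ve[i] < gain_threshold:
            k_elbow = ks[i]
            break
    return list(zip(ks, ve)), k_elbow


def compute_centroids(scans, partition: Partition, level: str = "group",
                      subject_id: str | None = None, condition: str | None = None) -> BrainStateSet:
    """Average assigned frames per cluster at a chosen aggregation level.

    ``group`` pools every frame; ``condition`` restricts to one condition;
    ``subject-condition`` restricts to one subject's scans in one condition.
    States with no frames at the requested level are flagged missing (their
    centroid rows are NaN), never silently zeroed.
    """
    if level not in ("group", "condition", "subject-condition"):
        raise ValueError(f"unknown level {level!r}")
    k = partition.k
    selected = []
    for scan in scans:
        if level == "condition" and scan.condition != condition:
            continue
        if level == "subject-condition" and (
            scan.subject_id != subject_id or scan.condition != condition
        ):
            continue
        selected.append((scan.values, partition.labels_for(scan.scan_id)))
    if not selected:
        raise ValueError("no scans match the requested level selection")
    X = np.vstack([v for v, _ in selected])
    lab = np.concatenate([l for _, l in selected])
    n_regions = X.shape[1]
    C = np.full((k, n_regions), np.nan)
    missing = np.zeros(k, dtype=bool)
    for j in range(1, k + 1):
        mask = lab == j
        if mask.any():
            C[j - 1] = X[mask].mean(axis=0)
        else:
            missing[j - 1] = True
    names = [f"state-{j}" for j in range(1, k + 1)]
    return BrainStateSet(centroids=C, level=level, names=names, missing=missing)


def rsn_alignment(centroid: np.ndarray, rsn_masks: dict) -> dict:
    """Cosine similarity of supra-/sub-mean centroid activity to RSN masks.

    The supra-mean part keeps the positive centroid entries (others zeroed);
    the sub-mean part is the absolute value of the negative entries.  Each
    part is compared to each binary mask by cosine similarity; an all-zero
    part has similarity 0 by convention.
    """
    c = np.asarray(centroid, dtype=float)
    supra = np.where(c > 0, c, 0.0)
    sub = np.where(c < 0, -c, 0.0)
    out = {}
    for name, mask in rsn_masks.items():
        m = np.asarray(mask, dtype=float)
        if m.shape != c.shape:
            raise ValueError(f"mask {name!r} does not match the centroid's regions")
        if not np.all(np.isin(m, (0.0, 1.0))):
            raise ValueError(f"mask {name!r} must be binary")
        out[name] = {"supra": _cosine(supra, m), "sub": _cosine(sub, m)}
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def pair_meta_states(centroids: np.ndarray):
    """Greedily pair sub-states by most negative Pearson correlation.

    Returns ``(meta_assignment, pair_correlations, warnings)`` where
    ``meta_assignment`` maps state label (1..k) to meta-state index (0..k/2-1).
    A pair whose correlation is >= 0 breaks the hierarchy assumption and is
    reported as a warning rather than an error.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = C.shape[0]
    if k % 2 != 0:
        raise ValueError("meta-state pairing requires an even number of states")
    R = np.corrcoef(C)
    remaining = set(range(k))
    pairs, corrs, warnings = [], [], []
    while remaining:
        best = None
        for i in sorted(remaining):
            for j in sorted(remaining):
                if j <= i:
                    continue
                if best is None or R[i, j] < best[0]:
                    best = (R[i, j], i, j)
        r, i, j = best
        remaining -= {i, j}
        pairs.append((i + 1, j + 1))
        corrs.append(float(r))
        if r >= 0:
            warnings.append(
                f"states {i + 1} and {j + 1} paired with correlation {r:.3f} >= 0"
            )
    assignment = {}
    for meta, (a, b) in enumerate(pairs):
        assignment[a] = meta
        assignment[b] = meta
    return assignment, corrs, warnings


def match_states(centroids: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Order states by maximal correlation with reference centroids.

    Solves the one-to-one assignment maximising summed Pearson correlation
    and returns ``order`` such that ``centroids[order[i]]`` matches
    ``reference[i]``.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    Rf = np.atleast_2d(np.asarray(reference, dtype=float))
    if C.shape != Rf.shape:
        raise ValueError("centroid sets must share k and region count")
    k = C.shape[0]
    corr = np.corrcoef(np.vstack([Rf, C]))[:k, k:]
    ref_idx, cen_idx = linear_sum_assignment(-corr)
    order = np.empty(k, dtype=int)
    order[ref_idx] = cen_idx
    return order
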