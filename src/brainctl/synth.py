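"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates every input the pipeline needs: a modular, log-normally weighted
structural connectome; anti-correlated pairs of brain-state centroids; Markov
state sequences; noisy demeaned BOLD realisations of those sequences;
spatially autocorrelated receptor maps on unit-sphere parcel coordinates; and
a paired two-condition cohort in which the "drug" condition's states are
amplitude-attenuated and may switch more frequently.

Study-design defaults mirror the emulated experiment: 15 subjects, two
conditions (one scan each), 220 frames per scan at TR = 2 s, k = 4 states on
200 regions.  The within-state noise standard deviation defaults to 1.0,
which with unit-variance centroids puts the frame-to-centroid correlation
near 0.7 — strong enough for clustering to recover the planted states, which
is all the generator is calibrated for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynthCohortSpec",
    "ParcellatedTimeSeries",
    "ParcelCoordinates",
    "sticky_transition_matrix",
    "gen_connectome",
    "gen_state_centroids",
    "gen_markov_state_sequence",
    "gen_bold_timeseries",
    "gen_parcel_coords",
    "gen_receptor_map",
    "gen_two_condition_cohort",
    "stationary_distribution",
]


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """Demeaned regional BOLD matrix (frames x regions) with scan identity."""

    values: np.ndarray
    tr_seconds: float
    subject_id: str
    condition: str
    scan_id: str

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("time series must be frames x regions with >= 2 frames")
        if np.any(~np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ParcelCoordinates:
    """Unit-sphere parcel positions split across hemispheres."""

    xyz: np.ndarray  # n_regions x 3, unit norm
    hemisphere: np.ndarray  # array of "left"/"right"

    def __post_init__(self):
        norms = np.linalg.norm(self.xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("parcel coordinates must lie on the unit sphere")
        if len(self.hemisphere) != self.xyz.shape[0]:
            raise ValueError("one hemisphere label per region required")


@dataclass(frozen=True)
class SynthCohortSpec:
    """Design of a paired two-condition synthetic cohort.

    ``drug_amplitude_factor`` scales the drug condition's centroids (in (0,1];
    1 means no amplitude effect).  Per-subject overrides allow coupling the
    amplitude effect with switching behaviour across subjects.
    """

    n_subjects: int = 15
    n_regions: int = 200
    k_states: int = 4
    frames_per_scan: int = 220
    tr_seconds: float = 2.0
    noise_sd: float = 1.0
    drug_amplitude_factor: float = 0.7
    transition_matrix_placebo: np.ndarray | None = None
    transition_matrix_drug: np.ndarray | None = None
    motion_covariate_sd: float = 0.05
    seed: int = 0
    # optional per-subject heterogeneity (arrays of length n_subjects)
    per_subject_amplitude: np.ndarray | None = None
    per_subject_drug_tm: list | None = None

    def __post_init__(self):
        if self.k_states % 2 != 0:
            raise ValueError("k_states must be even to permit anti-correlated pairs")
        if not (0 < self.drug_amplitude_factor <= 1):
            raise ValueError("drug_amplitude_factor must lie in (0, 1]")
        for name in ("transition_matrix_placebo", "transition_matrix_drug"):
            P = getattr(self, name)
            if P is not None:
                _check_stochastic(np.asarray(P), self.k_states, name)


@dataclass
class Cohort:
    """Paired scans plus per-subject motion covariates."""

    scans: list = field(default_factory=list)  # ParcellatedTimeSeries
    sequences: dict = field(default_factory=dict)  # scan_id -> planted labels
    centroids: np.ndarray | None = None  # planted placebo-scale centroids
    mean_fd: dict = field(default_factory=dict)  # subject_id -> motion covariate
    spec: SynthCohortSpec | None = None


def _check_stochastic(P: np.ndarray, k: int | None, name: str = "transition matrix"):
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be square")
    if k is not None and P.shape[0] != k:
        raise ValueError(f"{name} must be {k}x{k}")
    if np.any(P < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"{name} rows must sum to 1")


def sticky_transition_matrix(k: int, p_stay: float) -> np.ndarray:
    """Row-stochastic matrix with ``p_stay`` on the diagonal, rest uniform."""
    if not (0 <= p_stay <= 1):
        raise ValueError("p_stay must lie in [0, 1]")
    P = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(P, p_stay)
    return P


def gen_connectome(
    n_regions: int,
    n_modules: int = 1,
    density: float = 1.0,
    seed: int = 0,
    within_p: float = 0.8,
    max_retries: int = 20,
) -> np.ndarray:
    """Random modular connectome with log-normal weights (streamline-count-like).

    Edges are drawn at the requested density, biased toward within-module
    placement when ``n_modules > 1``; weights are log-normal, within-module
    weights doubled.  Regenerates on a disconnected draw up to
    ``max_retries`` times, then raises.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    modules = np.arange(n_regions) % max(n_modules, 1)
    for _ in range(max_retries):
        iu = np.triu_indices(n_regions, k=1)
        same = modules[iu[0]] == modules[iu[1]]
        # edge probabilities biased within modules while matching overall density
        p = np.where(same, within_p, 1.0 - within_p) if n_modules > 1 else np.ones(same.shape)
        p = p * density * p.size / p.sum()
        p = np.clip(p, 0.0, 1.0)
        present = rng.random(p.shape) < p
        w = rng.lognormal(mean=0.0, sigma=1.0, size=p.shape) * present
        w[same] *= 2.0  # heavier within-module weights
        A = np.zeros((n_regions, n_regions))
        A[iu] = w
        A = A + A.T
        if _is_connected(A):
            return A
    raise RuntimeError(f"failed to draw a connected connectome in {max_retries} attempts")


def _is_connected(A: np.ndarray) -> bool:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components((A > 0).astype(int), directed=False)
    return n_comp == 1


def gen_state_centroids(n_regions: int, k: int, seed: int = 0, perturb: float = 0.3) -> np.ndarray:
    """k planted brain-state centroids in anti-correlated pairs.

    Row ``2i`` is a random demeaned pattern; row ``2i+1`` is its negation plus
    a small perturbation, so each pair's Pearson correlation is <= -0.8 while
    the pairs stay mutually near-orthogonal.  Every centroid has zero mean
    across regions (matching demeaned BOLD) and unit per-region variance.
    """
    if k % 2 != 0:
        raise ValueError("k must be even: centroids come in anti-correlated pairs")
    rng = np.random.default_rng(seed)
    C = np.empty((k, n_regions))
    for pair in range(k // 2):
        base = rng.standard_normal(n_regions)
        partner = -base + perturb * rng.standard_normal(n_regions)
        C[2 * pair] = base
        C[2 * pair + 1] = partner
    C -= C.mean(axis=1, keepdims=True)
    C /= C.std(axis=1, keepdims=True)
    return C


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via eigen-decomposition."""
    _check_stochastic(np.asarray(P, dtype=float), None)
    evals, evecs = np.linalg.eig(np.asarray(P, dtype=float).T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_state_sequence(P: np.ndarray, n_frames: int, seed: int = 0) -> np.ndarray:
    """First-order Markov label sequence (labels 1..k), started at stationarity."""
    P = np.asarray(P, dtype=float)
    _check_stochastic(P, None)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k = P.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    labels = np.empty(n_frames, dtype=int)
    state = int(rng.choice(k, p=stationary_distribution(P)))
    labels[0] = state
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        state = min(state, k - 1)  # guard against u == 1 edge
        labels[t] = state
    return labels + 1


def gen_bold_timeseries(
    centroids: np.ndarray,
    sequence: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 2.0,
    subject_id: str = "s00",
    condition: str = "placebo",
    scan_id: str = "scan0",
    ar1: float = 0.0,
) -> ParcellatedTimeSeries:
    """Noisy BOLD realisation of a planted state sequence, demeaned per region.

    Frame ``t`` is ``centroid[label(t)]`` plus Gaussian noise; ``ar1`` adds
    optional temporal autocorrelation to the noise for robustness checks.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    seq = np.asarray(sequence, dtype=int)
    if seq.min() < 1 or seq.max() > C.shape[0]:
        raise ValueError("sequence labels must index the centroids (1..k)")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((len(seq), C.shape[1])) * noise_sd
    if ar1:
        for t in range(1, len(seq)):
            eps[t] = ar1 * eps[t - 1] + np.sqrt(1 - ar1**2) * eps[t]
    X = C[seq - 1] + eps
    X -= X.mean(axis=0, keepdims=True)
    return ParcellatedTimeSeries(
        values=X,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        condition=condition,
        scan_id=scan_id,
    )


def gen_parcel_coords(n_regions: int, seed: int = 0) -> ParcelCoordinates:
    """Random unit-sphere parcel positions, half per hemisphere (by x-sign)."""
    if n_regions % 2 != 0:
        raise ValueError("n_regions must be even to split across hemispheres")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    pts = rng.standard_normal((n_regions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:half, 0] = -np.abs(pts[:half, 0])  # left hemisphere: x < 0
    pts[half:, 0] = np.abs(pts[half:, 0])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hemi = np.array(["left"] * half + ["right"] * half)
    return ParcelCoordinates(xyz=pts, hemisphere=hemi)


def gen_receptor_map(
    coords: ParcelCoordinates, autocorr_scale: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Nonnegative receptor density map with spatial autocorrelation.

    Draws a Gaussian field whose covariance decays exponentially with
    great-circle distance (length scale ``autocorr_scale`` radians), then
    shifts it to be nonnegative.  ``autocorr_scale -> 0`` yields an
    approximately i.i.d. map.
    """
    rng = np.random.default_rng(seed)
    xyz = coords.xyz
    n = xyz.shape[0]
    if autocorr_scale <= 1e-9:
        z = rng.standard_normal(n)
    else:
        d = great_circle_distances(xyz, xyz)
        K = np.exp(-d / autocorr_scale) + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(K)
        z = L @ rng.standard_normal(n)
    return z - z.min()


def great_circle_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    dots = np.clip(a @ b.T, -1.0, 1.0)
    return np.arccos(dots)


def gen_two_condition_cohort(spec: SynthCohortSpec) -> Cohort:
    """Paired placebo/drug cohort of parcellated scans plus motion covariates.

    Placebo scans realise the planted centroids under the placebo transition
    matrix; drug scans use centroids scaled by the amplitude factor and the
    drug transition matrix.  A per-subject mean framewise-displacement
    covariate is drawn independently of all signals (a null covariate for
    partial-correlation analyses).
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k_states
    P_pl = (
        np.asarray(spec.transition_matrix_placebo, dtype=float)
        if spec.transition_matrix_placebo is not None
        else sticky_transition_matrix(k, 0.85)
    )
    P_dr = (
        np.asarray(spec.transition_matrix_drug, dtype=float)
        if spec.transition_matrix_drug is not None
        else P_pl
    )
    centroids = gen_state_centroids(spec.n_regions, k, seed=rng.integers(2**31))
    cohort = Cohort(centroids=centroids, spec=spec)
    for s in range(spec.n_subjects):
        sid = f"sub-{s:02d}"
        amp = (
            float(spec.per_subject_amplitude[s])
            if spec.per_subject_amplitude is not None
            else spec.drug_amplitude_factor
        )
        P_dr_s = (
            np.asarray(spec.per_subject_drug_tm[s], dtype=float)
            if spec.per_subject_drug_tm is not None
            else P_dr
        )
        for cond, P, scale in (("placebo", P_pl, 1.0), ("drug", P_dr_s, amp)):
            seq = gen_markov_state_sequence(P, spec.frames_per_scan, seed=rng.integers(2**31))
            scan_id = f"{sid}_{cond}"
            scan = gen_bold_timeseries(
                centroids * scale,
                seq,
                noise_sd=spec.noise_sd,
                seed=rng.integers(2**31),
                tr_seconds=spec.tr_seconds,
                subject_id=sid,
                condition=cond,
                scan_id=scan_id,
            )
            cohort.scans.append(scan)
            cohort.sequences[scan_id] = seq
        cohort.mean_fd[sid] = float(0.2 + spec.motion_covariate_sd * rng.standard_normal())
    return cohort
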