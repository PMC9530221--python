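# Methods

## Model and procedure

The pipeline treats parcellated, per-region-demeaned BOLD time series as a
sequence of visits to k recurrent activation patterns, and asks what those
visits would cost a linear dynamical system running on the structural
connectome.

**State extraction.** Frames from all scans are pooled and clustered with
Lloyd-style k-means under correlation distance: the distance between a frame
and a centroid is `1 − Pearson r` computed across regions, and centroids are
updated as plain arithmetic means of member frames. Each clustering is the
best of `n_replicates` random restarts (default 50) by within-cluster
distance sum; the whole procedure is repeated `n_runs` times independently
(default 10, seeds derived from the master seed by fixed offsets) and the
partition with the greatest *summed* adjusted mutual information to all
others is retained. AMI is label-permutation invariant, so this consensus
step is insensitive to arbitrary cluster numbering. k defaults to 4 and is
never chosen automatically: the elbow scan (variance explained for a range
of k, flagging the first k whose gain to k+1 falls below 1%) is advisory
output only. Frames that are constant across regions have no defined
correlation and are assigned by Euclidean distance; an empty cluster is
reseeded from the frame farthest from its current centroid, and the maximum
Lloyd iteration count is 300. These k-means policies are our own defaults
and are stated here because different implementations differ in exactly
these corners.

**Meta-states.** Centroids are paired greedily by most-negative Pearson
correlation. Greedy pairing is deterministic and exact for the intended
two-pair (k = 4) case; a pair with non-negative correlation is reported as a
warning because it breaks the assumption that sub-states come in opposing
pairs. Binarising a state sequence by meta-state membership discards only
within-pair switches, which are rare when the pairs are strongly
anti-correlated.

**Temporal dynamics.** Fractional occupancy, dwell time (mean contiguous run
length × TR, in seconds), appearance rate (run starts per minute) and the
empirical transition matrix are computed per subject and condition. Two
conventions matter and are applied uniformly to both conditions so that
paired contrasts stay unbiased: (1) **a run that starts a scan counts as an
appearance and contributes to dwell time** — the state is "entered" at
t = 0; (2) consecutive-frame pairs are only counted within scans, never
across scan boundaries. States never visited by a subject-condition
propagate as missing values (NaN), not zeros: an unobserved dwell time is
not a dwell time of 0 s.

**Transition energy.** The connectome is scaled to
`A_norm = A/(λ_max + 1) − I`, which places all eigenvalues strictly in the
left half-plane. The finite-horizon controllability Gramian is computed by
the Van Loan block-exponential identity; because the `−A'` block is
anti-stable, horizons beyond 2 time units are assembled by time-doubling
(`W(2t) = W(t) + e^{At} W(t) e^{A't}`), which involves only decaying
factors and is accurate to machine precision at any horizon. Energies are
`v' W(T)^{-1} v` via Cholesky factorisation, with the Gramian condition
number logged in provenance. The horizon defaults to T = 1 (normalised time
units); this is a convention, so a sensitivity check over T ∈ {0.5, 1, 3, 5}
is part of the test suite — entry orderings are strongly concordant between
adjacent horizons, although at long horizons energies increasingly depend
only on the target state. All k² ordered pairs are reported; any averaging
(e.g. the per-map mean used to rank receptor profiles) includes the
diagonal persistence energies.

An independent discretised oracle (zero-order-hold discretisation, least-
norm piecewise-constant control) validates the closed form to better than
1% at 2000 steps; the two computations share no code.

**Receptor weighting.** A receptor density map enters as
`B = diag(1 + minmax(map))`: min–max normalisation to [0, 1] is the simplest
map that makes the diagonal span exactly [1, 2] (division by the maximum
would not pin the lower endpoint). Constant maps are rejected with guidance
rather than silently mapped. Because `B₂B₂' ⪰ B₁B₁'` implies
`W₂(T) ⪰ W₁(T)` and hence `v'W₂⁻¹v ≤ v'W₁⁻¹v`, *any* receptor weighting
lowers every transition energy relative to uniform input; claims of spatial
specificity therefore require the spin null, not the uniform baseline.

**Spin nulls.** Each spin draws one uniform random rotation, applies it to
the left-hemisphere parcel coordinates and its sagittal mirror to the right,
then re-labels parcels within each hemisphere by greedy one-to-one
nearest-neighbour assignment over ascending great-circle distance. The
one-to-one variant (rather than plain nearest-neighbour, which can duplicate
values) guarantees every null map is a true permutation of the original —
the value multiset is preserved exactly, and Moran's I confirms most of the
spatial autocorrelation survives. Spin p-values use the add-one correction
`(r + 1)/(n + 1)`, which avoids p = 0 from finite ensembles and is
conservative under the null.

**Entropy.** LZ76 complexity counts the phrases of the exhaustive-history
parsing (implemented via substring search, validated against hand-parsed
fixtures including the classic 16-bit example with c = 6). Normalisation is
`c(n)/n`; the asymptotic `c(n)·log₂(n)/n` variant is available behind a
flag. The measure needs large effects at short sequence lengths; no
small-sample correction is applied.

**Statistics.** Paired two-sided t-tests (df = n − 1) contrast conditions;
Benjamini–Hochberg correction is applied within each metric family (the k
states of one dynamics metric; the k² transition-energy entries), matching
the per-panel scopes such analyses usually report. Relative differences are
`(a − b)/(a + b)`. Partial correlations residualise both variables on an
intercept plus the motion covariate and correlate the residuals, with
p-values from the t-approximation on n − 3 df; with a constant covariate
this reduces exactly to the plain Pearson correlation.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical skeleton the analysis relies on: a
15-subject paired design (one placebo, one drug scan each; 220 frames at
TR = 2 s; 200 regions), k = 4 planted centroids in two anti-correlated
pairs (pair correlations ≈ −0.96), Markov-driven state sequences started at
the stationary distribution, i.i.d. Gaussian within-state noise (an AR(1)
switch exists for robustness checks), a modular connectome with log-normal
weights mimicking streamline-count statistics, receptor maps as Gaussian
fields with exponentially decaying covariance on the sphere, and an
independent per-subject motion covariate (a null covariate by
construction). The drug condition attenuates centroid amplitudes by a
factor (default 0.7) and may switch transition matrices, optionally
per-subject so amplitude and switching effects can be coupled.

Default noise (sd 1.0 against unit-variance centroids) puts frame-to-
centroid correlations near 0.7 — calibrated only so clustering can recover
the planted states, not to match empirical fMRI SNR. Not emulated:
haemodynamic convolution, temporal autocorrelation of real BOLD, realistic
head motion, cortical geometry beyond a unit sphere, and any genuine
receptor-to-state spatial alignment. Consequently, passing tests show the
*machinery* is correct (energies drop exactly quadratically with amplitude,
flattening is detected, nulls calibrate); they cannot certify effect sizes
or specificity claims on real data — note that the synthetic spin test is
expectedly null because no receptor-state alignment is planted.

## Problem sizes and numerical choices

The acceptance script and tests run at deliberately modest sizes chosen as
the smallest that exercise each property cleanly: 50 random systems
(N ≤ 10) for the solver-oracle comparison, 100 systems for monotonicity, 20
cohorts at full study size (15 × 2 scans, 200 regions) for flattening
recovery with 3 k-means restarts per cohort, 10,000-frame chains for
parameter recovery, 1000 repeats for t-test calibration, and 40 repeats × 63
spins on a 30-region system for spin-p calibration. Gramian inversion
failures raise with the condition number; energies are clipped at 0 to
absorb −1e-16-scale roundoff; ties in state matching break to the lowest
index.

## Known limitations

- The linear model ignores nonlinear neural dynamics; transition energy is a
  model-based summary, not a metabolic quantity.
- The greedy meta-state pairing is only guaranteed optimal for two pairs.
- The elbow criterion is heuristic and reported, never enforced.
- Dwell-time estimates are right-censored by scan ends; no correction is
  applied (both conditions are censored identically).
- The spin test assumes parcel centroids on a sphere per hemisphere;
  surface-vertex spins and variogram-matching nulls are out of scope.
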