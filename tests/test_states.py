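"""Brain-state extraction: clustering, AMI selection, centroids, pairing."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_mutual_info_score

from brainctl import synth
from brainctl.states import (
    Partition,
    cluster_states,
    compute_centroids,
    elbow_scan,
    match_states,
    pair_meta_states,
    rsn_alignment,
    select_partition_by_ami,
    variance_explained,
)


def make_scans(n_regions=60, k=4, frames=300, noise=1.0, n_scans=2, seed=0):
    C = synth.gen_state_centroids(n_regions, k, seed=seed)
    scans, seqs = [], []
    P = synth.sticky_transition_matrix(k, 0.7)
    for i in range(n_scans):
        seq = synth.gen_markov_state_sequence(P, frames, seed=seed + 10 + i)
        scans.append(
            synth.gen_bold_timeseries(
                C, seq, noise_sd=noise, seed=seed + 20 + i,
                subject_id=f"s{i}", condition="placebo", scan_id=f"scan{i}",
            )
        )
        seqs.append(seq)
    return scans, np.concatenate(seqs), C


class TestClusterStates:
    def test_noiseless_case_recovers_planted_labels(self):
        scans, planted, _ = make_scans(noise=0.0, frames=100)
        part = cluster_states(scans, k=4, n_replicates=5, seed=0)
        assert adjusted_mutual_info_score(planted, part.labels) == pytest.approx(1.0)

    def test_noisy_recovery_at_study_snr(self):
        scans, planted, C = make_scans(n_regions=200, frames=1000, noise=1.0)
        part = cluster_states(scans, k=4, n_replicates=5, seed=0)
        assert adjusted_mutual_info_score(planted, part.labels) >= 0.9
        order = match_states(part.centroids, C)
        for i in range(4):
            r = np.corrcoef(part.centroids[order[i]], C[i])[0, 1]
            assert r >= 0.95

    def test_deterministic_for_fixed_seed(self):
        scans, _, _ = make_scans(frames=100)
        p1 = cluster_states(scans, k=3, n_replicates=3, seed=5)
        p2 = cluster_states(scans, k=3, n_replicates=3, seed=5)
        assert np.array_equal(p1.labels, p2.labels)
        assert np.allclose(p1.centroids, p2.centroids)

    def test_centroids_are_member_means(self):
        scans, _, _ = make_scans(frames=100)
        part = cluster_states(scans, k=4, n_replicates=3, seed=1)
        X = np.vstack([s.values for s in scans])
        for j in range(1, 5):
            assert np.allclose(part.centroids[j - 1], X[part.labels == j].mean(axis=0))

    def test_k_exceeding_frames_rejected(self):
        scans, _, _ = make_scans(frames=3, n_scans=1)
        with pytest.raises(ValueError):
            cluster_states(scans, k=10)

    def test_replicate_selection_minimizes_inertia(self):
        scans, _, _ = make_scans(frames=200, noise=2.0)
        best = cluster_states(scans, k=4, n_replicates=8, seed=3)
        singles = [cluster_states(scans, k=4, n_replicates=1, seed=3) for _ in range(1)]
        # best-of-8 can never be worse than the first replicate alone
        assert best.inertia <= singles[0].inertia + 1e-12


class TestAmiSelection:
    def _fake_partition(self, labels, seed=0):
        labels = np.asarray(labels)
        k = labels.max()
        return Partition(
            labels=labels, centroids=np.zeros((k, 2)), k=int(k),
            variance_explained=0.0, seed=seed, inertia=0.0,
        )

    def test_identical_partitions_return_first(self):
        parts = [self._fake_partition([1, 1, 2, 2], seed=i) for i in range(10)]
        assert select_partition_by_ami(parts) is parts[0]

    def test_label_permutation_invariance(self):
        a = self._fake_partition([1, 1, 2, 2, 3, 3])
        b = self._fake_partition([3, 3, 1, 1, 2, 2])
        assert adjusted_mutual_info_score(a.labels, b.labels) == pytest.approx(1.0)

    def test_consensus_beats_outlier(self, rng):
        common = rng.integers(1, 5, size=200)
        parts = [self._fake_partition(common, seed=i) for i in range(9)]
        parts.append(self._fake_partition(rng.integers(1, 5, size=200), seed=99))
        winner = select_partition_by_ami(parts)
        assert np.array_equal(winner.labels, common)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            select_partition_by_ami(
                [self._fake_partition([1, 2]), self._fake_partition([1, 2, 1])]
            )


class TestVarianceExplained:
    def test_perfect_partition_explains_everything(self):
        # single scan so demeaning leaves the frames of each state identical
        scans, _, _ = make_scans(noise=0.0, frames=80, n_scans=1)
        part = cluster_states(scans, k=4, n_replicates=3, seed=0)
        assert variance_explained(part, scans) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_sums(self):
        scans, _, _ = make_scans(frames=100, noise=1.0)
        part = cluster_states(scans, k=3, n_replicates=3, seed=2)
        X = np.vstack([s.values for s in scans])
        within = sum(
            ((X[part.labels == j] - part.centroids[j - 1]) ** 2).sum() for j in range(1, 4)
        )
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert variance_explained(part, scans) == pytest.approx(1 - within / total, abs=1e-10)

    def test_monotone_nondecreasing_in_k(self):
        scans, _, _ = make_scans(frames=200)
        table, _ = elbow_scan(scans, k_range=range(2, 7), n_replicates=3, seed=0)
        ve = [v for _, v in table]
        assert all(ve[i + 1] >= ve[i] - 0.01 for i in range(len(ve) - 1))


class TestElbow:
    def test_planted_k_produces_elbow(self):
        scans, _, _ = make_scans(n_regions=100, frames=600, noise=0.5)
        table, _ = elbow_scan(scans, k_range=range(2, 7), n_replicates=3, seed=0)
        ve = dict(table)
        gain_34 = ve[4] - ve[3]
        gain_45 = ve[5] - ve[4]
        assert gain_45 < gain_34

    def test_unstructured_data_decays_smoothly(self, rng):
        X = rng.standard_normal((300, 30))
        X -= X.mean(axis=0)
        scan = synth.ParcellatedTimeSeries(
            values=X, tr_seconds=2.0, subject_id="s", condition="c", scan_id="x"
        )
        table, _ = elbow_scan([scan], k_range=range(2, 6), n_replicates=3, seed=0)
        gains = np.diff([v for _, v in table])
        assert gains.max() < 0.15  # no sharp elbow


class TestComputeCentroids:
    def test_group_level_equals_partition_centroids(self):
        scans, _, _ = make_scans(frames=100)
        part = cluster_states(scans, k=4, n_replicates=3, seed=0)
        bs = compute_centroids(scans, part, level="group")
        assert np.allclose(bs.centroids, part.centroids)
        assert not bs.missing.any()

    def test_missing_state_flagged_not_zeroed(self):
        scans, _, _ = make_scans(frames=100, n_scans=2)
        part = cluster_states(scans, k=4, n_replicates=3, seed=0)
        # restrict subject s0 to frames from one state only
        part.labels[part.scan_slices["scan0"]] = 2
        bs = compute_centroids(
            scans, part, level="subject-condition", subject_id="s0", condition="placebo"
        )
        assert bs.missing[0] and not bs.missing[1]
        assert np.isnan(bs.centroids[0]).all()

    def test_condition_centroids_track_group_when_exchangeable(self, small_cohort):
        spec = synth.SynthCohortSpec(
            n_subjects=4, n_regions=60, frames_per_scan=150,
            drug_amplitude_factor=1.0, seed=3,
        )
        cohort = synth.gen_two_condition_cohort(spec)
        part = cluster_states(cohort.scans, k=4, n_replicates=3, seed=0)
        grp = compute_centroids(cohort.scans, part, level="group")
        cond = compute_centroids(cohort.scans, part, level="condition", condition="drug")
        for j in range(4):
            r = np.corrcoef(grp.centroids[j], cond.centroids[j])[0, 1]
            assert r >= 0.95


class TestRsnAlignment:
    def test_centroid_equal_to_mask_scores_one(self):
        mask = np.array([1.0, 1, 0, 0, 0, 0])
        out = rsn_alignment(mask, {"net": mask})
        assert out["net"]["supra"] == pytest.approx(1.0)
        assert out["net"]["sub"] == 0.0

    def test_disjoint_support_scores_zero(self):
        centroid = np.array([0.0, 0, 1, 2, 0, 0])
        mask = np.array([1.0, 1, 0, 0, 0, 0])
        assert rsn_alignment(centroid, {"net": mask})["net"]["supra"] == 0.0

    def test_mixed_centroid_matches_hand_computation(self):
        centroid = np.array([2.0, -1, 0, 3, -2, 1])
        mask = np.array([1.0, 0, 1, 1, 0, 0])
        # supra = (2,0,0,3,0,1): dot = 5, |supra| = sqrt(14), |mask| = sqrt(3)
        # sub = (0,1,0,0,2,0): dot = 0
        out = rsn_alignment(centroid, {"net": mask})["net"]
        assert out["supra"] == pytest.approx(5 / np.sqrt(14 * 3))
        assert out["sub"] == pytest.approx(0.0)

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError):
            rsn_alignment(np.ones(3), {"net": np.array([0.5, 1, 0])})


class TestMetaStatePairing:
    def test_exact_opposites_pair_up(self, rng):
        c = rng.standard_normal(30)
        d = rng.standard_normal(30)
        d -= d @ c / (c @ c) * c  # orthogonalise
        C = np.vstack([c, -c, d, -d])
        assignment, corrs, warnings = pair_meta_states(C)
        assert assignment[1] == assignment[2]
        assert assignment[3] == assignment[4]
        assert assignment[1] != assignment[3]
        assert all(r < -0.99 for r in corrs)
        assert not warnings

    def test_noisy_planted_pairs_recovered(self):
        C = synth.gen_state_centroids(50, 4, seed=0)
        noisy = C + 0.2 * np.random.default_rng(1).standard_normal(C.shape)
        assignment, _, _ = pair_meta_states(noisy)
        assert assignment[1] == assignment[2] and assignment[3] == assignment[4]

    def test_positive_pair_warns(self, rng):
        C = np.abs(rng.standard_normal((2, 20))) + 1.0  # all-positive patterns
        _, corrs, warnings = pair_meta_states(C)
        if corrs[0] >= 0:
            assert warnings

    def test_odd_k_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_meta_states(rng.standard_normal((3, 10)))


class TestMatchStates:
    def test_identity_on_itself(self, rng):
        C = rng.standard_normal((4, 20))
        assert np.array_equal(match_states(C, C), np.arange(4))

    def test_recovers_shuffle(self, rng):
        C = rng.standard_normal((5, 20))
        perm = rng.permutation(5)
        order = match_states(C[perm], C)
        assert np.array_equal(perm[order], np.arange(5))

    def test_matches_noisy_copies(self, rng):
        C = synth.gen_state_centroids(100, 4, seed=0)
        noisy = C + 0.4 * rng.standard_normal(C.shape)
        perm = rng.permutation(4)
        order = match_states(noisy[perm], C)
        assert np.array_equal(perm[order], np.arange(4))
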