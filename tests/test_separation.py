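"""Per-residue inter-layer separation: distances, burn-in, replicas, flags."""

import numpy as np
import pandas as pd
import pytest

from fibrilkit import (
    DetachmentSpec,
    GeneratorSpec,
    aggregate_replicas,
    compare_variants,
    differential_regions,
    flag_loosened,
    make_fibril,
    make_replica_set,
    make_trajectory,
    max_after_burnin,
    residue_distances,
    separation_profile,
)
from fibrilkit.errors import CorrespondenceError, FibrilError
from fibrilkit.separation import SeparationProfile


@pytest.fixture
def quiet_model():
    return make_fibril(GeneratorSpec(sequence=30, n_layers=4, twist=0.0, rise=4.8))


class TestResidueDistances:
    def test_static_trajectory_constant(self, quiet_model):
        traj = make_trajectory(quiet_model, n_frames=10, jitter_sigma_nm=0.0, seed=0)
        d = residue_distances(traj, (2, 3))
        assert np.allclose(d.values, d.values[:, :1])
        # zero twist: equivalent CAs differ by the rise only (0.48 nm)
        assert np.allclose(d.values, 0.48, atol=1e-9)

    def test_rigid_shift_closed_form(self, quiet_model):
        """Displacing one layer by +0.3 nm in z changes every distance exactly."""
        traj = make_trajectory(quiet_model, n_frames=3, jitter_sigma_nm=0.0, seed=0)
        idx = 0
        for lay in quiet_model.layers:
            for res in lay.residues:
                for _ in res.atoms:
                    if lay.layer_index == 3:
                        traj.frames[1, idx, 2] += 3.0  # +0.3 nm in frame 1
                    idx += 1
        d = residue_distances(traj, (2, 3))
        assert np.allclose(d.values[:, 0], 0.48)
        assert np.allclose(d.values[:, 1], 0.78)

    def test_matches_brute_force(self, quiet_model):
        traj = make_trajectory(quiet_model, n_frames=4, jitter_sigma_nm=0.05, seed=8)
        d = residue_distances(traj, (1, 2))
        topo = traj.topology
        # brute force over frames/residues
        flat = [(lay.layer_index, res.seq, a.name)
                for lay in topo.layers for res in lay.residues for a in res.atoms]
        pos = {k: i for i, k in enumerate(flat)}
        for f in range(traj.n_frames):
            for seq in d.index:
                a = traj.frames[f, pos[(1, seq, "CA")]]
                b = traj.frames[f, pos[(2, seq, "CA")]]
                assert d.loc[seq].iloc[f] == pytest.approx(np.linalg.norm(a - b) / 10.0)

    def test_planted_detachment_only_grows_those_series(self, quiet_model):
        det = DetachmentSpec(layer=3, residue_range=(10, 15), amplitude_nm=1.0, onset_ns=0.0)
        traj = make_trajectory(quiet_model, n_frames=11, dt_ns=1.0,
                               jitter_sigma_nm=0.0, detachment=det, seed=0)
        d = residue_distances(traj, (2, 3))
        final = d.iloc[:, -1]
        assert (final.loc[10:15] > 1.0).all()
        others = final.drop(index=range(10, 16))
        assert np.allclose(others, 0.48, atol=1e-9)


class TestMaxAfterBurnin:
    def test_spike_before_burnin_excluded(self):
        times = np.arange(0.0, 201.0, 1.0)
        vals = np.full_like(times, 0.5)
        vals[30] = 2.0  # spike at 30 ns
        s = pd.Series(vals, index=times)
        assert max_after_burnin(s, burnin_ns=50.0) == pytest.approx(0.5)

    def test_monotone_series_gives_final_value(self):
        s = pd.Series(np.linspace(0, 1, 101), index=np.arange(101.0))
        assert max_after_burnin(s, 50.0) == pytest.approx(1.0)

    def test_constant_series(self):
        s = pd.Series(np.full(101, 0.48), index=np.arange(101.0))
        assert max_after_burnin(s, 50.0) == pytest.approx(0.48)

    def test_too_short_trajectory_raises(self):
        s = pd.Series(np.ones(5), index=np.arange(5.0))
        with pytest.raises(FibrilError):
            max_after_burnin(s, 50.0)

    def test_invariant_to_pre_burnin_changes(self, quiet_model):
        """Any modification of frames before burn-in leaves the maxima unchanged."""
        traj = make_trajectory(quiet_model, n_frames=101, jitter_sigma_nm=0.02, seed=4)
        d1 = max_after_burnin(residue_distances(traj, (2, 3)), 50.0)
        traj.frames[:50] += np.random.default_rng(0).normal(0, 5.0, traj.frames[:50].shape)
        d2 = max_after_burnin(residue_distances(traj, (2, 3)), 50.0)
        assert np.allclose(d1, d2)


class TestAggregateReplicas:
    def test_identical_replicas_sem_zero(self):
        s = pd.Series([0.5, 0.6], index=pd.Index([1, 2], name="residue_seq"))
        prof = aggregate_replicas([s, s.copy(), s.copy()])
        assert np.allclose(prof.replica_sem, 0.0)
        assert np.allclose(prof.replica_mean, [0.5, 0.6])

    def test_two_replica_arithmetic(self):
        a = pd.Series([0.4], index=pd.Index([1], name="residue_seq"))
        b = pd.Series([0.6], index=pd.Index([1], name="residue_seq"))
        prof = aggregate_replicas([a, b])
        assert prof.replica_mean[0] == pytest.approx(0.5)
        assert prof.replica_sem[0] == pytest.approx(0.1)

    def test_single_replica_sem_missing(self):
        prof = SeparationProfile(np.array([1]), np.array([[0.5]]),
                                 burnin_ns=50.0, layer_pair=(0, 1))
        assert np.isnan(prof.replica_sem).all()

    def test_sem_approaches_sd_over_sqrt_n(self):
        """Replica SEM of simulated maxima matches sd/sqrt(6) within MC error."""
        rng = np.random.default_rng(12)
        sems = []
        for _ in range(200):
            x = rng.normal(0.5, 0.1, size=6)
            s = [pd.Series([v], index=pd.Index([1], name="residue_seq")) for v in x]
            sems.append(aggregate_replicas(s).replica_sem[0])
        assert np.mean(sems) == pytest.approx(0.1 / np.sqrt(6), rel=0.1)

    def test_mismatched_residues_raise(self):
        a = pd.Series([0.4], index=pd.Index([1], name="residue_seq"))
        b = pd.Series([0.6], index=pd.Index([2], name="residue_seq"))
        with pytest.raises(CorrespondenceError):
            aggregate_replicas([a, b])


class TestFlagLoosened:
    def _profile(self, means):
        seqs = np.arange(1, len(means) + 1)
        return SeparationProfile(seqs, np.array([means]), burnin_ns=50.0,
                                 layer_pair=(4, 5))

    def test_intact_profile_flags_nothing(self):
        prof = self._profile([0.5] * 20)
        flagged, regions = flag_loosened(prof)
        assert flagged == set() and regions == []

    def test_single_residue_region(self):
        means = [0.5] * 10
        means[4] = 0.71
        flagged, regions = flag_loosened(self._profile(means))
        assert flagged == {5} and regions == [(5, 5)]

    def test_threshold_is_strict(self):
        means = [0.5] * 5
        means[2] = 0.7
        flagged, _ = flag_loosened(self._profile(means))
        assert flagged == set()


class TestEndToEndRecovery:
    def test_detachment_region_recovered(self):
        """Six 200 ns replicas with a planted 1 nm detachment of residues 84-107
        flag exactly that region at the 0.7 nm threshold; the intact control
        flags nothing."""
        model = make_fibril(GeneratorSpec(n_layers=6))
        det = DetachmentSpec(layer=5, residue_range=(84, 107),
                             amplitude_nm=1.0, onset_ns=100.0)
        loose = make_replica_set(model, n_replicas=6, detachment=det, seed=42,
                                 n_frames=201, dt_ns=1.0)
        prof = separation_profile(loose, (4, 5), burnin_ns=50.0)
        flagged, regions = flag_loosened(prof, threshold_nm=0.7)
        assert regions == [(84, 107)]
        intact = make_replica_set(model, n_replicas=6, seed=42,
                                  n_frames=201, dt_ns=1.0)
        prof0 = separation_profile(intact, (4, 5), burnin_ns=50.0)
        flagged0, regions0 = flag_loosened(prof0, threshold_nm=0.7)
        assert flagged0 == set() and regions0 == []

    def test_pooled_mode(self):
        model = make_fibril(GeneratorSpec(sequence=20, n_layers=3))
        trajs = make_replica_set(model, n_replicas=2, seed=0, n_frames=101)
        pooled = separation_profile(trajs, (1, 2), burnin_ns=50.0, pooled=True)
        per_rep = separation_profile(trajs, (1, 2), burnin_ns=50.0)
        assert pooled.n_replicas == 1
        assert (pooled.replica_mean >= per_rep.replica_mean - 1e-12).all()


class TestCompareVariants:
    def _profile(self, means):
        seqs = np.arange(1, len(means) + 1)
        return SeparationProfile(seqs, np.array([means]), burnin_ns=50.0,
                                 layer_pair=(4, 5))

    def test_identical_profiles_zero_delta(self):
        p = self._profile([0.5] * 10)
        rep = compare_variants(p, self._profile([0.5] * 10))
        assert np.allclose(rep["delta_nm"], 0.0)
        assert not rep["differential"].any()

    def test_differential_region_found(self):
        """WT-like loosening at 84-107 vs intact patient: differential region."""
        n = 130
        wt = [0.5] * n
        for r in range(84, 108):
            wt[r - 1] = 1.1
        rep = compare_variants(self._profile(wt), self._profile([0.5] * n))
        assert differential_regions(rep) == [(84, 107)]

    def test_antisymmetry(self):
        a = self._profile([0.4, 0.9, 0.5])
        b = self._profile([0.6, 0.5, 0.5])
        r1 = compare_variants(a, b)
        r2 = compare_variants(b, a)
        assert np.allclose(r1["delta_nm"], -r2["delta_nm"])

    def test_range_mismatch_raises(self):
        a = self._profile([0.5] * 5)
        b = SeparationProfile(np.arange(2, 7), np.array([[0.5] * 5]),
                              burnin_ns=50.0, layer_pair=(4, 5))
        with pytest.raises(CorrespondenceError):
            compare_variants(a, b)
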