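"""Trajectory analytics: alignment, series, RMSF, change points, medoids."""

import numpy as np
import pytest

from _oracles import brute_force_medoid
from redoxstruct.structio import Trajectory
from redoxstruct.synthetic_data import make_loop_trajectory, make_toy_structure
from redoxstruct.trajectory import (block_representative, core_superpose,
                                    detect_transitions, pair_distance_series,
                                    residue_rmsd_series, rmsf)

MOTIF = [("A", n) for n in range(112, 132)]


@pytest.fixture(scope="module")
def stepped():
    """Aligned trajectory with the default concerted step at 6 µs."""
    t = make_loop_trajectory(n_frames=200, dt=0.1, transition_time=6.0,
                             noise_sigma=0.1, seed=11)
    return core_superpose(t)


class TestCoreSuperpose:
    def test_pure_tumbling_removed(self):
        t = make_loop_trajectory(n_frames=30, dt=0.1, transition_time=1.0,
                                 amplitudes=[0.0] * 20, noise_sigma=0.0,
                                 seed=2, global_motion=True)
        aligned = core_superpose(t)
        ref = aligned.frames[0]
        for f in aligned.frames:
            assert np.sqrt(((f - ref) ** 2).sum(axis=1).mean()) < 1e-8

    def test_identity_trajectory_unchanged(self):
        t = make_loop_trajectory(n_frames=10, dt=0.1, transition_time=0.5,
                                 amplitudes=[0.0] * 20, noise_sigma=0.0, seed=3)
        aligned = core_superpose(t)
        for a, b in zip(t.frames, aligned.frames):
            assert np.allclose(a, b, atol=1e-10)

    def test_planted_loop_moves_but_core_does_not(self, stepped):
        core_rmsd = stepped.metadata["core_rmsd"]
        assert np.max(core_rmsd) < 0.5
        series = residue_rmsd_series(stepped, MOTIF)
        truth = stepped.metadata["truth"]
        after = stepped.times >= truth["transition_time"]
        for j, (_, num) in enumerate(MOTIF):
            amp = truth["amplitudes"][num]
            if amp > 0:
                assert np.median(series.matrix[after, j]) == pytest.approx(
                    amp, rel=0.25)

    def test_tiny_core_rejected(self):
        t = make_loop_trajectory(n_frames=5, dt=0.1, transition_time=0.2,
                                 seed=1)
        with pytest.raises(ValueError, match=">= 3"):
            core_superpose(t, core=[("A", 95), ("A", 96)])


class TestResidueRmsdSeries:
    def test_reference_row_is_zero(self, stepped):
        series = residue_rmsd_series(stepped, MOTIF, reference_frame=0)
        assert np.allclose(series.matrix[0], 0.0)

    def test_single_rigid_displacement_equals_its_magnitude(self):
        t = make_loop_trajectory(n_frames=10, dt=1.0, transition_time=5.0,
                                 motif_residues=[120],
                                 amplitudes=[3.0], noise_sigma=0.0, seed=7)
        aligned = core_superpose(t)
        series = residue_rmsd_series(aligned, [("A", 120)])
        assert series.matrix[:5, 0] == pytest.approx(0.0, abs=1e-9)
        assert series.matrix[5:, 0] == pytest.approx(3.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, stepped, rng):
        series = residue_rmsd_series(stepped, MOTIF)
        rows = {}
        i = 0
        for res, a in stepped.topology.iter_atoms():
            rows.setdefault((res.chain_id, res.number), []).append(i)
            i += 1
        for j in rng.integers(0, len(MOTIF), 5):
            key = MOTIF[j]
            idx = rows[key]
            for fi in rng.integers(0, stepped.n_frames, 5):
                diffs = stepped.frames[fi][idx] - stepped.frames[0][idx]
                expected = np.sqrt((diffs ** 2).sum(axis=1).mean())
                assert series.matrix[fi, j] == pytest.approx(expected, abs=1e-9)

    def test_missing_residue_rejected(self, stepped):
        with pytest.raises(KeyError):
            residue_rmsd_series(stepped, [("A", 9999)])


class TestPairDistance:
    def test_static_pair_constant(self):
        t = make_loop_trajectory(n_frames=20, dt=0.1, transition_time=1.0,
                                 amplitudes=[0.0] * 20, noise_sigma=0.0, seed=5)
        d = pair_distance_series(t, "A:112:CA", "A:131:CA")
        assert np.allclose(d, d[0])

    def test_planted_linear_ramp(self):
        s = make_toy_structure(n_chains=1, residues_per_chain=5)
        base = np.array([a.position for _, a in s.iter_atoms()])
        rows = {}
        i = 0
        for res, a in s.iter_atoms():
            rows[(res.number, a.name)] = i
            i += 1
        away = base[rows[(105, "CA")]] - base[rows[(101, "CA")]]
        away /= np.linalg.norm(away)
        frames = []
        for k in range(10):
            f = base.copy()
            f[rows[(105, "CA")]] += k * away
            frames.append(f)
        t = Trajectory(topology=s, frames=frames, times=np.arange(10.0))
        d = pair_distance_series(t, "A:105:CA", "A:101:CA")
        assert np.allclose(np.diff(d), 1.0, atol=1e-9)

    def test_matches_frame_by_frame_oracle(self, stepped, rng):
        d = pair_distance_series(stepped, "A:115:CA", "A:125:CA")
        idx = stepped.atom_index()
        ia = idx[("A", 115, "", "CA")]
        ib = idx[("A", 125, "", "CA")]
        for fi in rng.integers(0, stepped.n_frames, 10):
            expected = np.linalg.norm(stepped.frames[fi][ia]
                                      - stepped.frames[fi][ib])
            assert d[fi] == pytest.approx(expected, abs=1e-12)

    def test_missing_atom_rejected(self, stepped):
        with pytest.raises(KeyError):
            pair_distance_series(stepped, "A:115:SG", "A:120:SG")


class TestRmsf:
    def test_static_trajectory_zero(self):
        t = make_loop_trajectory(n_frames=10, dt=0.1, transition_time=0.5,
                                 amplitudes=[0.0] * 20, noise_sigma=0.0, seed=1)
        out = rmsf(t, MOTIF)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        sigma = 0.25
        t = make_loop_trajectory(n_frames=2000, dt=0.01, transition_time=1.0,
                                 amplitudes=[0.0] * 20, noise_sigma=sigma,
                                 seed=21)
        out = rmsf(t, MOTIF)
        mean_rmsf = np.mean(list(out.values()))
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_flexible_motif_exceeds_core(self, stepped):
        truth = stepped.metadata["truth"]
        mobile = [("A", n) for n, a in truth["amplitudes"].items() if a > 0]
        core = stepped.metadata["core"][:10]
        out = rmsf(stepped, mobile + core)
        motif_mean = np.mean([out[k] for k in mobile])
        core_mean = np.mean([out[k] for k in core])
        assert motif_mean > 3 * core_mean

    def test_empty_window_rejected(self, stepped):
        with pytest.raises(ValueError, match="empty"):
            rmsf(stepped, MOTIF, window=(5, 5))


class TestDetectTransitions:
    def test_flat_noise_has_no_transitions(self):
        t = make_loop_trajectory(n_frames=100, dt=0.1, transition_time=5.0,
                                 amplitudes=[0.0] * 20, noise_sigma=0.3,
                                 seed=13)
        aligned = core_superpose(t)
        series = residue_rmsd_series(aligned, MOTIF)
        res = detect_transitions(series, min_jump=1.0)
        assert res.events == []

    def test_concerted_step_recovered_at_planted_time(self, stepped):
        series = residue_rmsd_series(stepped, MOTIF)
        res = detect_transitions(series, min_jump=1.0, min_segment=5,
                                 concert_window=0.5, concert_fraction=0.75)
        assert len(res.events) >= 1
        main = max(res.events, key=lambda e: e.fraction)
        assert main.time == pytest.approx(6.0, abs=0.1)
        assert main.concerted
        # the two zero-amplitude flank residues must not participate
        assert main.fraction == pytest.approx(18 / 20, abs=0.051)

    def test_staggered_steps_are_separate_unconcerted_events(self):
        rng = np.random.default_rng(17)
        times = 0.1 * np.arange(200)
        n_res = 21
        mat = rng.normal(2.0, 0.05, (200, n_res))
        for j in range(n_res):
            step_at = (2.0, 8.0, 14.0)[j // 7]
            mat[times >= step_at, j] += 4.0
        mat[0] = 0.0
        from redoxstruct.trajectory import SeriesResult
        series = SeriesResult(residue_ids=[("A", 100 + j) for j in range(n_res)],
                              times=times, matrix=np.abs(mat),
                              reference_frame=0)
        res = detect_transitions(series, min_jump=1.0, concert_window=1.0,
                                 concert_fraction=0.75)
        assert len(res.events) == 3
        assert not any(e.concerted for e in res.events)
        assert [round(e.time, 1) for e in res.events] == [2.0, 8.0, 14.0]

    def test_min_segment_floor(self, stepped):
        series = residue_rmsd_series(stepped, MOTIF)
        with pytest.raises(ValueError):
            detect_transitions(series, min_segment=1)

    def test_recovery_within_two_frames_at_good_snr(self):
        hits = 0
        for seed in range(10):
            t = make_loop_trajectory(n_frames=150, dt=0.1,
                                     transition_time=6.0, noise_sigma=1.0,
                                     seed=seed)
            aligned = core_superpose(t)
            series = residue_rmsd_series(aligned, MOTIF)
            res = detect_transitions(series, min_jump=1.5)
            truth_frame = t.metadata["truth"]["transition_frame"]
            ok = any(abs(np.searchsorted(t.times, e.time) - truth_frame) <= 2
                     for e in res.events if e.concerted)
            hits += ok
        assert hits >= 9


class TestBlockRepresentative:
    def test_single_frame_window(self, stepped):
        t0 = float(stepped.times[42])
        block = block_representative(stepped, (t0, t0))
        assert block.medoid_frame == 42
        assert block.mean_intra_block_rmsd == 0.0

    def test_medoid_of_jittered_copies_close_to_template(self):
        t = make_loop_trajectory(n_frames=40, dt=0.1, transition_time=0.5,
                                 amplitudes=[0.0] * 20, noise_sigma=0.2,
                                 seed=3)
        block = block_representative(t, (1.0, 3.9))
        ref = t.frames[block.medoid_frame]
        base = t.frames[0]
        assert np.sqrt(((ref - base) ** 2).sum(axis=1).mean()) < 3 * 0.2 * np.sqrt(3)

    def test_matches_independent_medoid_search(self, stepped):
        lo, hi = 17.0, 19.9
        sel = np.where((stepped.times >= lo) & (stepped.times <= hi))[0]
        coords = np.array([stepped.frames[i] for i in sel])
        expected = sel[brute_force_medoid(coords)]
        block = block_representative(stepped, (lo, hi))
        assert block.medoid_frame == expected

    def test_two_equal_subclusters_tie_breaks_earliest(self):
        s = make_toy_structure(n_chains=1, residues_per_chain=4)
        base = np.array([a.position for _, a in s.iter_atoms()])
        frames = [base.copy(), base.copy(), base + 5.0, base + 5.0]
        t = Trajectory(topology=s, frames=frames, times=np.arange(4.0))
        block = block_representative(t, (0.0, 3.0))
        assert block.medoid_frame == 0

    def test_post_transition_block_is_displaced_state(self, stepped):
        truth = stepped.metadata["truth"]
        block = block_representative(stepped, (17.0, 19.9))
        series = residue_rmsd_series(stepped, MOTIF)
        j = series.residue_ids.index(("A", 125))
        assert series.matrix[block.medoid_frame, j] == pytest.approx(
            truth["amplitudes"][125], rel=0.3)

    def test_empty_window_rejected(self, stepped):
        with pytest.raises(ValueError, match="no frames"):
            block_representative(stepped, (100.0, 101.0))
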