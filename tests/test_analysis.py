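"""Trajectory sorting, RMSD, distance-matrix PCA, and exchange stats."""

import math

import numpy as np
import pytest

from grestkit.analysis import (
    AnalysisError,
    distance_matrix_pca,
    energy_rmsd_correlation,
    exchange_statistics,
    rmsd,
    sort_by_parameter,
)
from grestkit.sampling import ExchangeLog, Trajectory


def make_trajectory(coords, param_index, betas=None):
    coords = np.asarray(coords, float)
    T, M = coords.shape[:2]
    betas = np.linspace(1.0, 0.5, M) if betas is None else np.asarray(betas)
    if M == 1:
        betas = np.array([1.0])
    return Trajectory(
        steps=np.arange(1, T + 1) * 10,
        coords=coords,
        param_index=np.asarray(param_index, int),
        components=np.zeros((T, M, 1)),
        evv=np.zeros((T, M)),
        scaled_energy=np.zeros((T, M)),
        exponents=np.array([1.0]),
        betas=betas,
        beta_0=1.0,
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestSortByParameter:
    def test_identity_mapping_returns_raw_streams(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3, 4, 3))
        pidx = np.tile(np.arange(3), (5, 1))
        st = sort_by_parameter(make_trajectory(coords, pidx))
        for m in range(3):
            np.testing.assert_array_equal(st.coords[m], coords[:, m])
            assert st.replica[m].tolist() == [m] * 5

    def test_hand_traced_single_swap(self):
        """Two replicas, one swap accepted between frames 2 and 3: the
        beta_1 stream is replica 0's frames 1-2 then replica 1's 3+."""
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(5, 2, 3, 3))
        pidx = np.array([[0, 1], [0, 1], [1, 0], [1, 0], [1, 0]])
        st = sort_by_parameter(make_trajectory(coords, pidx))
        expect_b1 = np.stack([coords[0, 0], coords[1, 0],
                              coords[2, 1], coords[3, 1], coords[4, 1]])
        np.testing.assert_array_equal(st.beta1[0], expect_b1)
        assert st.replica[0].tolist() == [0, 0, 1, 1, 1]

    def test_every_frame_used_exactly_once(self):
        rng = np.random.default_rng(2)
        M, T = 4, 30
        pidx = np.stack([rng.permutation(M) for _ in range(T)])
        coords = rng.normal(size=(T, M, 2, 3))
        st = sort_by_parameter(make_trajectory(coords, pidx))
        seen = np.stack([st.replica[m] for m in range(M)])
        for t in range(T):
            assert sorted(seen[:, t].tolist()) == list(range(M))

    def test_mapping_reconstructed_from_log_snapshots(self):
        """Without a per-frame record, the rung mapping is recovered from
        the exchange log (frames precede the sweep at their own step)."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(4, 2, 2, 3))
        traj = make_trajectory(coords, np.zeros((0, 0)))
        traj.param_index = np.zeros((0, 0), int)
        log = ExchangeLog(n_params=2)
        log.record_snapshot(10, np.array([1, 0]))   # swap accepted at step 10
        log.record_snapshot(20, np.array([1, 0]))
        log.record_snapshot(30, np.array([0, 1]))   # swapped back at step 30
        log.record_snapshot(40, np.array([0, 1]))
        st = sort_by_parameter(traj, log)
        # frame steps are 10,20,30,40; each governed by the prior snapshot
        assert st.replica[0].tolist() == [0, 1, 1, 0]

    def test_broken_bijection_detected(self):
        coords = np.zeros((2, 2, 2, 3))
        pidx = np.array([[0, 0], [0, 1]])
        with pytest.raises(AnalysisError):
            sort_by_parameter(make_trajectory(coords, pidx))


class TestRmsd:
    def test_identical_frames_give_zero(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(6, 3))
        assert rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_invisible(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(7, 3))
        R = random_rotation(rng)
        moved = ref @ R.T + np.array([3.0, -1.0, 2.0])
        assert rmsd(moved, ref) == pytest.approx(0.0, abs=1e-10)

    def test_four_point_value_matches_rotation_grid_oracle(self):
        """Brute-force search over rotations (coarse grid + local
        refinement) reproduces the Kabsch answer."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        ref = np.array([[0.0, 0, 0], [1.2, 0, 0], [1.0, 1.3, 0], [0.2, 0.9, 1.1]])
        frame = np.array([[0.1, -0.2, 0.0], [1.4, 0.1, 0.2],
                          [0.9, 1.2, -0.3], [0.0, 1.0, 1.0]])

        fc = frame - frame.mean(axis=0)
        rc = ref - ref.mean(axis=0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((fc @ R.T - rc) ** 2, axis=1)))

        best = np.inf
        grid = np.linspace(-math.pi, math.pi, 9)
        for a in grid:
            for b in grid:
                for c in grid:
                    v = np.array([a, b, c])
                    if np.linalg.norm(v) > math.pi:
                        continue
                    res = minimize(cost, v, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert rmsd(frame, ref) == pytest.approx(best, abs=1e-6)

    def test_symmetric_when_selections_coincide(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), rel=1e-10)

    def test_fit_and_measure_selections_are_independent(self, mini_loop):
        ml = mini_loop
        fit = ml.framework_atoms
        out = ml.loop_atoms
        v1 = rmsd(ml.start, ml.reference, fit, out)
        v2 = rmsd(ml.start, ml.reference, fit, fit)
        assert v1 > 0.5 and v2 < 0.2

    def test_collinear_fit_atoms_rejected(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(AnalysisError):
            rmsd(line + 0.5, line)


class TestDistanceMatrixPca:
    def test_constant_trajectory_has_no_variance(self):
        frames = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (6, 1, 1))
        with pytest.warns(RuntimeWarning):
            scores, eig = distance_matrix_pca(frames, n_components=2)
        assert scores.shape[1] == 0 or np.allclose(scores, 0)
        assert np.allclose(eig, 0)

    def test_two_conformations_separate_on_pc1(self):
        """Frames drawn around two rigid conformations form two clusters
        bimodally separated along the first component."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3))
        b = a + np.array([0.0, 0.0, 1.5]) * (np.arange(6) % 2)[:, None]
        frames, labels = [], []
        for i in range(60):
            base = a if i % 2 == 0 else b
            R = random_rotation(rng)
            frames.append((base + 0.03 * rng.normal(size=a.shape)) @ R.T)
            labels.append(i % 2)
        scores, eig = distance_matrix_pca(np.asarray(frames), n_components=2)
        labels = np.asarray(labels)
        gap = abs(scores[labels == 0, 0].mean() - scores[labels == 1, 0].mean())
        spread = scores[labels == 0, 0].std() + scores[labels == 1, 0].std()
        assert gap > 3 * spread
        assert eig[0] > 5 * eig[1]

    def test_eigenvalues_account_for_total_variance(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(40, 5, 3))
        iu, ju = np.triu_indices(5, k=1)
        feats = np.linalg.norm(frames[:, iu] - frames[:, ju], axis=-1)
        total = feats.var(axis=0, ddof=1).sum()
        scores, eig = distance_matrix_pca(frames, n_components=10)
        assert eig.sum() == pytest.approx(total, rel=1e-9)
        # scores are uncorrelated across components
        cov = np.cov(scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * max(1.0, cov.max())

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(size=(3, 4, 3))
        with pytest.warns(RuntimeWarning):
            scores, eig = distance_matrix_pca(frames, n_components=50)
        assert scores.shape[1] <= 2  # rank limited by 3 frames


class TestMiniLoopPhenomenology:
    @pytest.fixture(scope="class")
    def dihedral_run(self, mini_loop):
        from grestkit.sampling import ParameterLadder, run_grest

        ml = mini_loop
        lad = ParameterLadder.geometric(6, 1.0, 10.0)
        traj, _ = run_grest(ml.system, ml.selection_with("dihedral"), lad,
                            60_000, exchange_interval=100, save_interval=100,
                            seed=31, x0=ml.start)
        return sort_by_parameter(traj)

    def test_pca_resolves_cis_and_trans_clusters(self, mini_loop, dihedral_run):
        """The physical stream of a dihedral-tempered run forms two PC1
        clusters matching the cis and trans dihedral states."""
        ml = mini_loop
        coords = dihedral_run.beta1[0]
        phis = ml.bistable_angles(coords)
        trans = np.abs(np.abs(phis) - math.pi) < math.pi / 2
        assert 0.05 < trans.mean() < 0.95  # both states visited
        scores, eig = distance_matrix_pca(coords, ml.loop_atoms, 2)
        gap = abs(scores[trans, 0].mean() - scores[~trans, 0].mean())
        pooled = scores[trans, 0].std() + scores[~trans, 0].std()
        assert gap > pooled

    def test_lower_energy_frames_sit_closer_to_the_stable_structure(
            self, mini_loop):
        """With all categories tempered, RMSD to the global-minimum
        structure correlates positively with the scaled total energy at
        beta_1 (low energy <-> near the stable state)."""
        from grestkit.model import compile_model
        from grestkit.sampling import ParameterLadder, run_grest

        ml = mini_loop
        model = compile_model(ml.system, ml.selection)
        candidates = [ml.start, ml.reference]
        energies = [float(model.scaled_energy(c, 1.0)) for c in candidates]
        reference = candidates[int(np.argmin(energies))]
        lad = ParameterLadder.from_temperatures(
            [1, 1.3, 1.7, 2.5, 3.9, 6.9, 14.7, 50.0]
        )
        traj, _ = run_grest(ml.system, ml.selection, lad, 80_000,
                            exchange_interval=100, save_interval=100,
                            seed=13, x0=ml.start)
        st = sort_by_parameter(traj)
        _, _, r = energy_rmsd_correlation(
            st.beta1[0][100:], st.energy[0][100:], reference,
            ml.framework_atoms, ml.loop_atoms,
        )
        assert r > 0


class TestExchangeStatistics:
    def test_empty_log(self):
        st = exchange_statistics(ExchangeLog(n_params=4))
        assert st.attempts.tolist() == [0, 0, 0]
        assert np.isnan(st.ratios).all()
        assert st.round_trips.tolist() == [0, 0, 0, 0]

    def test_direct_count(self):
        log = ExchangeLog(n_params=3)
        for i in range(10):
            log.record_attempt(i, 0, 0.5, i < 3)
        st = exchange_statistics(log)
        assert st.attempts[0] == 10 and st.acceptances[0] == 3
        assert st.ratios[0] == pytest.approx(0.3)
        assert st.ratio_se[0] == pytest.approx(math.sqrt(0.3 * 0.7 / 10))

    def test_round_trip_counting(self):
        log = ExchangeLog(n_params=3)
        path = [0, 1, 2, 1, 0, 1, 2, 2, 1, 0]  # two full 0 -> 2 -> 0 trips
        for t, m in enumerate(path):
            log.record_snapshot(t, np.array([m, 0, 0]))
        st = exchange_statistics(log)
        assert st.round_trips[0] == 2

    def test_path_that_never_reaches_top_counts_nothing(self):
        log = ExchangeLog(n_params=3)
        for t, m in enumerate([0, 1, 1, 0, 1, 0]):
            log.record_snapshot(t, np.array([m, 0, 0]))
        assert exchange_statistics(log).round_trips[0] == 0


class TestEnergyRmsdCorrelation:
    def test_exact_linear_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(5, 3))
        frames = np.stack([ref + np.array([0.1 * t, 0, 0]) * np.array([1, -1, 1, -1, 1])[:, None]
                           for t in range(1, 20)])
        r_series = rmsd(frames, ref)
        energies = 2.0 * r_series + 1.0
        _, _, r = energy_rmsd_correlation(frames, energies, ref)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_independent_series_are_uncorrelated(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(size=(4, 3))
        n = 10_000
        frames = ref[None] + 0.2 * rng.normal(size=(n, 4, 3))
        energies = rng.normal(size=n)
        _, _, r = energy_rmsd_correlation(frames, energies, ref)
        assert abs(r) < 0.05

    def test_zero_variance_flagged(self):
        ref = np.random.default_rng(10).normal(size=(4, 3))
        frames = np.tile(ref, (5, 1, 1))
        with pytest.warns(RuntimeWarning):
            _, _, r = energy_rmsd_correlation(frames, np.ones(5), ref)
        assert math.isnan(r)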