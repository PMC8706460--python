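"""Post-processing of replica-exchange output.

Replica trajectories are demultiplexed into constant-parameter streams
(the lowest solute-"temperature" stream, beta_1, is the physical one and
the primary analysis target), compared to a reference structure by
Kabsch-superposed RMSD, embedded by PCA on pairwise-distance features,
and summarized by exchange statistics and the energy-RMSD diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sampling import ExchangeLog, Trajectory

__all__ = [
    "SortedTrajectory",
    "ExchangeStats",
    "sort_by_parameter",
    "kabsch_superpose",
    "rmsd",
    "distance_matrix_pca",
    "exchange_statistics",
    "energy_rmsd_correlation",
]


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trajectory sorting


@dataclass
class SortedTrajectory:
    """Constant-parameter trajectories after demultiplexing.

    For rung m: coords[m] is (T, N, d), replica[m] the source replica of
    each frame, energy[m] the scaled potential E_m of that frame.
    ``beta1`` views the first (physical-ensemble) stream.
    """

    steps: np.ndarray
    coords: list
    replica: list
    energy: list
    betas: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.coords)

    @property
    def beta1(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords, source replica, scaled energy) of the beta_1 stream."""
        return self.coords[0], self.replica[0], self.energy[0]


def sort_by_parameter(trajectory: Trajectory,
                      exchange_log: ExchangeLog | None = None) -> SortedTrajectory:
    """Demultiplex per-replica frames into per-rung streams.

    The frame of replica a at time t is assigned to the rung m(a, t) it
    held while being propagated. The mapping is taken from the
    trajectory's own per-frame record; if absent, it is reconstructed
    from the exchange log's sweep snapshots (the latest snapshot at or
    before each frame time).
    """
    pidx = trajectory.param_index
    if pidx is None or pidx.size == 0:
        if exchange_log is None:
            raise AnalysisError("trajectory carries no rung mapping and no log given")
        pidx = _mapping_from_log(trajectory, exchange_log)
    T, M = pidx.shape
    coords, replica, energy = [], [], []
    for m in range(M):
        rows, cols = np.where(pidx == m)
        if rows.size != T:
            raise AnalysisError(
                f"rung mapping is not a bijection at some frame (rung {m})"
            )
        coords.append(trajectory.coords[rows, cols])
        replica.append(cols.copy())
        lam = trajectory.betas[m] / trajectory.beta_0
        comp = trajectory.components[rows, cols]
        evv = trajectory.evv[rows, cols]
        energy.append(comp @ (lam ** trajectory.exponents) + evv)
    return SortedTrajectory(
        steps=trajectory.steps.copy(), coords=coords, replica=replica,
        energy=energy, betas=trajectory.betas.copy(),
    )


def _mapping_from_log(trajectory: Trajectory, log: ExchangeLog) -> np.ndarray:
    snap_steps = np.asarray(log.snapshot_steps)
    if snap_steps.size == 0:
        raise AnalysisError("exchange log holds no mapping snapshots")
    snaps = np.asarray(log.snapshots)
    order = np.argsort(snap_steps, kind="stable")
    snap_steps, snaps = snap_steps[order], snaps[order]
    out = np.empty((trajectory.n_frames, snaps.shape[1]), int)
    for t, step in enumerate(trajectory.steps):
        # frames are saved before the exchange attempt at their own step,
        # so the governing snapshot is the last one strictly before it
        i = int(np.searchsorted(snap_steps, step, side="left")) - 1
        if i < 0:
            # frames before the first exchange ran under the initial
            # identity mapping
            out[t] = np.arange(snaps.shape[1])
            continue
        out[t] = snaps[i]
    return out


# ---------------------------------------------------------------------------
# RMSD


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translations aligning mobile onto reference
    (least-squares, proper rotation via SVD with determinant correction).

    Returns (R, t) with aligned = mobile @ R.T + t.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise AnalysisError("superposition needs >= 3 matching atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if S[1] < 1e-12:
        raise AnalysisError("fit atoms are collinear; superposition is degenerate")
    return R, rc - R @ mc


def rmsd(frames: np.ndarray, reference: np.ndarray,
         fit_selection=None, rmsd_selection=None) -> np.ndarray:
    """Per-frame RMSD after Kabsch superposition.

    The rigid fit is computed on ``fit_selection`` and the deviation
    measured on ``rmsd_selection`` (both default to all atoms; the
    default ties them together).
    """
    frames = np.asarray(frames, float)
    single = frames.ndim == 2
    F = frames[None] if single else frames
    reference = np.asarray(reference, float)
    n = reference.shape[0]
    fit_sel = np.arange(n) if fit_selection is None else np.asarray(fit_selection, int)
    out_sel = fit_sel if rmsd_selection is None else np.asarray(rmsd_selection, int)
    if fit_sel.size == 0 or out_sel.size == 0:
        raise AnalysisError("selections must be non-empty")
    vals = np.empty(F.shape[0])
    ref_fit = reference[fit_sel]
    ref_out = reference[out_sel]
    for t in range(F.shape[0]):
        R, trans = kabsch_superpose(F[t, fit_sel], ref_fit)
        aligned = F[t, out_sel] @ R.T + trans
        vals[t] = np.sqrt(np.mean(np.sum((aligned - ref_out) ** 2, axis=1)))
    return float(vals[0]) if single else vals


# ---------------------------------------------------------------------------
# distance-matrix PCA


def distance_matrix_pca(frames: np.ndarray, atom_selection=None,
                        n_components: int = 2):
    """PCA on the flattened upper triangle of per-frame pairwise-distance
    matrices (superposition-free conformational embedding).

    Returns (scores (T, n_components), eigenvalues (n_components,)).
    Eigenvalues are those of the feature covariance (ddof = 1), in
    non-increasing order; each component is sign-fixed so its
    largest-magnitude loading is positive.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise AnalysisError("need at least 2 frames of (N, 3) coordinates")
    sel = (np.arange(frames.shape[1]) if atom_selection is None
           else np.asarray(atom_selection, int))
    if sel.size < 2:
        raise AnalysisError("need at least 2 selected atoms")
    x = frames[:, sel]
    iu, ju = np.triu_indices(sel.size, k=1)
    feats = np.linalg.norm(x[:, iu] - x[:, ju], axis=-1)
    feats = feats - feats.mean(axis=0)
    U, S, Vt = np.linalg.svd(feats, full_matrices=False)
    eig = S**2 / (frames.shape[0] - 1)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if n_components > rank:
        import warnings

        warnings.warn(
            f"n_components={n_components} exceeds feature rank {rank}; truncating",
            RuntimeWarning,
        )
        n_components = max(rank, 0)
    scores = U[:, :n_components] * S[:n_components]
    # deterministic sign: largest-|loading| positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    return scores, eig[:n_components]


# ---------------------------------------------------------------------------
# exchange statistics


@dataclass
class ExchangeStats:
    """Per-pair acceptance and per-replica rung diffusion summaries."""

    attempts: np.ndarray          # (M-1,)
    acceptances: np.ndarray       # (M-1,)
    ratios: np.ndarray            # (M-1,), nan where no attempts
    ratio_se: np.ndarray          # binomial standard errors, nan likewise
    replica_paths: np.ndarray     # (T_sweeps, M) rung of each replica over time
    round_trips: np.ndarray       # (M,) completed beta_1 -> beta_M -> beta_1 trips

    @property
    def mean_acceptance(self) -> float:
        ok = self.attempts > 0
        return float(np.mean(self.ratios[ok])) if ok.any() else float("nan")


def exchange_statistics(log: ExchangeLog) -> ExchangeStats:
    """Summarize an exchange log: per-neighbor-pair acceptance ratios with
    binomial errors, each replica's rung path, and round-trip counts."""
    attempts, accepts = log.pair_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(attempts > 0, accepts / np.maximum(attempts, 1), np.nan)
        se = np.where(
            attempts > 0,
            np.sqrt(np.maximum(ratios * (1.0 - ratios), 0.0) / np.maximum(attempts, 1)),
            np.nan,
        )
    if log.snapshots:
        paths = np.asarray(log.snapshots)
    else:
        paths = np.zeros((0, log.n_params), int)
    M = log.n_params
    trips = np.zeros(M, int)
    if paths.size and M > 1:
        for a in range(M):
            seq = paths[:, a]
            stage = 0  # 0: waiting to touch bottom, 1: heading to top, 2: returning
            for m in seq:
                if stage == 0 and m == 0:
                    stage = 1
                elif stage == 1 and m == M - 1:
                    stage = 2
                elif stage == 2 and m == 0:
                    trips[a] += 1
                    stage = 1
    return ExchangeStats(
        attempts=attempts, acceptances=accepts, ratios=ratios, ratio_se=se,
        replica_paths=paths, round_trips=trips,
    )


# ---------------------------------------------------------------------------
# energy-RMSD diagnostic


def energy_rmsd_correlation(coords: np.ndarray, energies: np.ndarray,
                            reference: np.ndarray, fit_selection=None,
                            rmsd_selection=None):
    """(RMSD, scaled energy) pairs of a sorted stream and their Pearson r.

    Returns (rmsd_series, energies, r); r is nan (flagged by a warning)
    when either series has zero variance.
    """
    energies = np.asarray(energies, float)
    r_series = rmsd(coords, reference, fit_selection, rmsd_selection)
    r_series = np.atleast_1d(r_series)
    if energies.shape != r_series.shape:
        raise AnalysisError("energy series and frame count differ")
    if np.ptp(energies) == 0 or np.ptp(r_series) == 0:
        import warnings

        warnings.warn("zero-variance series; correlation undefined", RuntimeWarning)
        return r_series, energies, float("nan")
    r, _ = stats.pearsonr(r_series, energies)
    return r_series, energies, float(r)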