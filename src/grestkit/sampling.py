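"""Replica propagation, parameter exchange, and ladder optimization.

All replicas run at a common bath temperature T_0 = 1/beta_0; only the
solute scaling parameter beta_m (the solute "temperature" T_m = 1/beta_m,
k_B = 1) differs between rungs. An exchange swaps the scaling parameters
of two replicas holding adjacent rungs, accepted by the Metropolis
criterion on the detailed-balance exponent

    Delta = sum_e beta_0**(1-e) * (beta_n**e - beta_m**e)
                 * (C_e(x_a) - C_e(x_b))

where C_e collects the energy of all terms sharing the tempering
exponent e = k/l (e = 1 is the solute-solute bucket). The solvent-solvent
energy E_vv cancels and never enters the criterion. With a single
exponent e = 1 this is the REST2 exponent, and when the solute is the
whole system it is the plain temperature-exchange (T-REMD) exponent.

Exchange sweeps alternate even rung pairs (1,2), (3,4), ... with odd
pairs (2,3), (4,5), ...; coordinates stay with their replicas and only
the rung assignment moves, so velocities are untouched by a swap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import EnergyDecomposition, ModelError, SoluteSelection, compile_model

__all__ = [
    "ParameterLadder",
    "ExchangeLog",
    "Trajectory",
    "GRESTSampler",
    "LadderOptimizationResult",
    "exchange_delta",
    "metropolis_probability",
    "metropolis_accept",
    "propagate",
    "run_grest",
    "optimize_ladder",
]


class SamplingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter ladder


@dataclass(frozen=True)
class ParameterLadder:
    """Ordered scaling parameters beta_1 > beta_2 > ... > beta_M.

    The first rung is pinned to the bath: beta_1 = beta_0, so the
    lowest-solute-"temperature" trajectory samples the physical ensemble.
    """

    betas: np.ndarray
    beta_0: float

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, float).ravel()
        object.__setattr__(self, "betas", betas)
        if betas.size < 1:
            raise ModelError("ladder needs at least one rung")
        if np.any(betas <= 0) or self.beta_0 <= 0:
            raise ModelError("inverse temperatures must be positive")
        if not math.isclose(betas[0], self.beta_0, rel_tol=0, abs_tol=1e-12):
            raise ModelError("beta_1 must equal the bath beta_0")
        if betas.size > 1 and np.any(np.diff(betas) >= 0):
            raise ModelError("betas must be strictly decreasing")

    @property
    def n_replicas(self) -> int:
        return self.betas.size

    @property
    def temperatures(self) -> np.ndarray:
        """Solute "temperatures" T_m = 1/beta_m (k_B = 1)."""
        return 1.0 / self.betas

    @property
    def lambdas(self) -> np.ndarray:
        """Scaling factors beta_m / beta_0."""
        return self.betas / self.beta_0

    @classmethod
    def geometric(cls, n_replicas: int, beta_0: float = 1.0,
                  t_max_factor: float = 5.0) -> "ParameterLadder":
        """Rungs geometric in solute temperature from T_0 to t_max_factor*T_0."""
        if n_replicas < 1:
            raise ModelError("n_replicas must be >= 1")
        if n_replicas == 1:
            return cls(np.array([beta_0]), beta_0)
        t0 = 1.0 / beta_0
        temps = t0 * np.exp(np.linspace(0.0, math.log(t_max_factor), n_replicas))
        betas = 1.0 / temps
        betas[0] = beta_0
        return cls(betas, beta_0)

    @classmethod
    def from_temperatures(cls, temps, beta_0: float | None = None) -> "ParameterLadder":
        temps = np.asarray(temps, float)
        b0 = 1.0 / temps[0] if beta_0 is None else beta_0
        return cls(1.0 / temps, b0)

    def with_temperatures(self, temps) -> "ParameterLadder":
        return ParameterLadder(1.0 / np.asarray(temps, float), self.beta_0)


# ---------------------------------------------------------------------------
# exchange criterion


def exchange_delta(decomp_a: EnergyDecomposition, decomp_b: EnergyDecomposition,
                   beta_m: float, beta_n: float, beta_0: float) -> float:
    """Detailed-balance exponent for swapping rungs m (replica a) and n
    (replica b):

        Delta = (beta_n - beta_m) (E_uu(x_a) - E_uu(x_b))
              + sum_i beta_0**(1 - k_i/l_i)
                      (beta_n**(k_i/l_i) - beta_m**(k_i/l_i))
                      (E_uv,i(x_a) - E_uv,i(x_b))

    The solvent-solvent bucket cancels and does not appear. When every
    cross term has k = l the sum collapses into the first (REST2) form.
    """
    if beta_m <= 0 or beta_n <= 0 or beta_0 <= 0:
        raise ModelError("inverse temperatures must be positive")
    ka = [(k, l) for _, k, l in decomp_a.uv_terms]
    kb = [(k, l) for _, k, l in decomp_b.uv_terms]
    if ka != kb:
        raise ModelError("uv term lists of the two decompositions are not aligned")
    delta = (beta_n - beta_m) * (decomp_a.E_uu - decomp_b.E_uu)
    for (ea, k, l), (eb, _, _) in zip(decomp_a.uv_terms, decomp_b.uv_terms):
        e = k / l
        delta += beta_0 ** (1.0 - e) * (beta_n**e - beta_m**e) * (ea - eb)
    return float(delta)


def metropolis_probability(delta: float) -> float:
    """Exchange acceptance probability: 1 if Delta <= 0, else exp(-Delta)."""
    return 1.0 if delta <= 0 else float(math.exp(-delta))


def metropolis_accept(delta: float, rng: np.random.Generator) -> bool:
    """Metropolis decision; consumes one uniform draw only when Delta > 0."""
    if delta <= 0:
        return True
    return float(rng.random()) <= math.exp(-delta)


def _grouped_delta(beta_m: float, beta_n: float, beta_0: float,
                   exponents: np.ndarray, comps_a: np.ndarray,
                   comps_b: np.ndarray) -> float:
    """Exchange exponent from exponent-grouped energy components."""
    w = beta_0 ** (1.0 - exponents) * (beta_n**exponents - beta_m**exponents)
    return float(np.dot(w, comps_a - comps_b))


# ---------------------------------------------------------------------------
# logs and trajectories


@dataclass
class ExchangeLog:
    """Record of every exchange attempt plus rung-mapping snapshots."""

    n_params: int
    steps: list = field(default_factory=list)       # sampler step of each attempt
    pairs: list = field(default_factory=list)       # lower rung index (0-based)
    deltas: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    snapshot_steps: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)   # param_of_replica after each sweep

    def record_attempt(self, step: int, pair: int, delta: float, acc: bool) -> None:
        self.steps.append(step)
        self.pairs.append(pair)
        self.deltas.append(delta)
        self.accepted.append(acc)

    def record_snapshot(self, step: int, param_of_replica: np.ndarray) -> None:
        self.snapshot_steps.append(step)
        self.snapshots.append(param_of_replica.copy())

    def pair_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(attempts, acceptances) per neighbor pair (m, m+1)."""
        attempts = np.zeros(max(self.n_params - 1, 0), int)
        accepts = np.zeros_like(attempts)
        for p, a in zip(self.pairs, self.accepted):
            attempts[p] += 1
            accepts[p] += int(a)
        return attempts, accepts

    def acceptance_ratios(self) -> np.ndarray:
        att, acc = self.pair_counts()
        with np.errstate(invalid="ignore"):
            return np.where(att > 0, acc / np.maximum(att, 1), np.nan)


@dataclass
class Trajectory:
    """Frames saved during a run, still organised per replica.

    coords[t, a] are replica a's coordinates at frame t, sampled while it
    held rung param_index[t, a]; scaled_energy[t, a] is its own scaled
    potential E_m(a) at that frame.
    """

    steps: np.ndarray            # (T,)
    coords: np.ndarray           # (T, M, N, d)
    param_index: np.ndarray      # (T, M) rung held by each replica
    components: np.ndarray       # (T, M, n_exponents)
    evv: np.ndarray              # (T, M)
    scaled_energy: np.ndarray    # (T, M)
    exponents: np.ndarray        # (n_exponents,)
    betas: np.ndarray
    beta_0: float

    @property
    def n_frames(self) -> int:
        return self.steps.size

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# the replica-exchange sampler


class GRESTSampler:
    """Propagates M replicas under their scaled Hamiltonians and attempts
    neighbor exchanges of the scaling parameters.

    Parameters
    ----------
    system, sel : the model and its solute selection (any system kind
        accepted by :func:`grestkit.model.compile_model`).
    ladder : ParameterLadder
    mode : "langevin" (BAOAB splitting) or "metropolis_mc"
        (single-particle Gaussian-displacement sweeps).
    dt, friction : Langevin time step and friction (reduced units).
    mc_step : MC displacement standard deviation.
    seed : master seed; one counter-based stream per replica plus one for
        the exchange controller, all spawned from it.
    """

    def __init__(self, system, sel: SoluteSelection, ladder: ParameterLadder,
                 mode: str = "langevin", dt: float = 0.005, friction: float = 1.0,
                 mc_step: float = 0.25, seed: int = 0, x0: np.ndarray | None = None):
        if mode not in ("langevin", "metropolis_mc"):
            raise ModelError(f"unknown propagation mode {mode!r}")
        self.model = compile_model(system, sel)
        self.ladder = ladder
        self.mode = mode
        self.dt = float(dt)
        self.friction = float(friction)
        self.mc_step = float(mc_step)
        self.seed = int(seed)
        M = ladder.n_replicas
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(M + 1)
        self.replica_rngs = [np.random.Generator(np.random.Philox(c)) for c in children[:M]]
        self.controller_rng = np.random.Generator(np.random.Philox(children[M]))

        n, d = self.model.n_atoms, self.model.ndim
        if x0 is None:
            x0 = getattr(self.model, "reference_positions", None)
            if x0 is None:
                x0 = self.model.system.positions
        x0 = np.asarray(x0, float)
        if x0.shape == (n, d):
            self.X = np.repeat(x0[None], M, axis=0).copy()
        elif x0.shape == (M, n, d):
            self.X = x0.copy()
        else:
            raise ModelError(f"x0 must have shape ({n}, {d}) or ({M}, {n}, {d})")
        t0 = 1.0 / ladder.beta_0
        m = self.model.masses[None, :, None]
        self.V = np.stack(
            [rng.normal(scale=np.sqrt(t0 / m[0, :, 0])[:, None], size=(n, d))
             for rng in self.replica_rngs]
        )
        self.param_of_replica = np.arange(M)
        self.step_count = 0
        self._mc_total_trials = 0
        self._mc_accepted_trials = 0

    # -- propagation -------------------------------------------------------

    #: optional per-replica scaling-factor override (used by the
    #: single-replica ``propagate`` helper); None means "use the ladder".
    lambda_override: np.ndarray | None = None

    @property
    def _lambdas_now(self) -> np.ndarray:
        if self.lambda_override is not None:
            return self.lambda_override
        return self.ladder.lambdas[self.param_of_replica]

    def propagate_block(self, n_steps: int) -> None:
        if self.mode == "langevin":
            self._langevin_block(n_steps)
        else:
            self._mc_block(n_steps)
        self.step_count += n_steps

    def _langevin_block(self, n_steps: int) -> None:
        lam = self._lambdas_now
        t0 = 1.0 / self.ladder.beta_0
        c1 = math.exp(-self.friction * self.dt)
        X, V = self.X, self.V
        shape = X.shape[1:]
        if getattr(self.model, "use_kernels", False):
            from . import _kernels

            c2_atom = np.sqrt((1.0 - c1 * c1) * t0 / self.model.masses)
            inv_m = 1.0 / self.model.masses
            done = 0
            while done < n_steps:  # chunked so pre-drawn noise stays small
                chunk = min(n_steps - done, 2000)
                noise = np.stack(
                    [rng.normal(size=(chunk,) + shape) for rng in self.replica_rngs]
                )
                _kernels.baoab_block(X, V, np.ascontiguousarray(lam, float), noise,
                                     self.dt, c1, c2_atom, inv_m,
                                     self.model._kernel_args)
                done += chunk
        else:
            m = self.model.masses[None, :, None]
            c2 = np.sqrt((1.0 - c1 * c1) * t0 / m)
            half = 0.5 * self.dt
            F = self.model.scaled_forces(X, lam)
            for _ in range(n_steps):
                V += half * F / m
                X += half * V
                noise = np.stack([rng.normal(size=shape) for rng in self.replica_rngs])
                V *= c1
                V += c2 * noise
                X += half * V
                F = self.model.scaled_forces(X, lam)
                V += half * F / m
        if not np.all(np.isfinite(X)):
            raise SamplingError(
                "Langevin integration diverged (non-finite coordinates); "
                "reduce dt or soften the potential"
            )

    def _mc_block(self, n_sweeps: int) -> None:
        if getattr(self.model, "independent_dofs", False):
            self._mc_block_independent(n_sweeps)
            return
        lam = self._lambdas_now
        beta0 = self.ladder.beta_0
        n = self.model.n_atoms
        X = self.X
        E = self.model.scaled_energy(X, lam)
        for _ in range(n_sweeps):
            for j in range(n):
                disp = np.stack(
                    [rng.normal(scale=self.mc_step, size=self.model.ndim)
                     for rng in self.replica_rngs]
                )
                old = X[:, j, :].copy()
                X[:, j, :] = old + disp
                E_new = self.model.scaled_energy(X, lam)
                with np.errstate(over="ignore"):
                    p = np.exp(-beta0 * np.minimum(E_new - E, 700.0))
                u = np.array([rng.random() for rng in self.replica_rngs])
                rej = ~np.isfinite(E_new) | (u > p)
                X[rej, j, :] = old[rej]
                E = np.where(rej, E, E_new)
                self._mc_total_trials += len(rej)
                self._mc_accepted_trials += int((~rej).sum())

    def _mc_block_independent(self, n_sweeps: int) -> None:
        # separable Hamiltonians (harmonic baths): all coordinates of a
        # replica can be trial-moved simultaneously with per-coordinate
        # Metropolis tests, since the energy is a sum over coordinates.
        lam = self._lambdas_now
        beta0 = self.ladder.beta_0
        X = self.X
        for _ in range(n_sweeps):
            dE_old = self.model.per_dof_scaled_energy(X, lam)
            disp = np.stack(
                [rng.normal(scale=self.mc_step, size=X.shape[1:])
                 for rng in self.replica_rngs]
            )
            X_new = X + disp
            dE_new = self.model.per_dof_scaled_energy(X_new, lam)
            u = np.stack(
                [rng.random(size=X.shape[1]) for rng in self.replica_rngs]
            )
            acc = u <= np.exp(-beta0 * np.minimum(dE_new - dE_old, 700.0))
            X[acc] = X_new[acc]
            self._mc_total_trials += acc.size
            self._mc_accepted_trials += int(acc.sum())

    # -- exchange ----------------------------------------------------------

    def exchange_sweep(self, parity: int, log: ExchangeLog | None = None) -> None:
        """Attempt swaps on rung pairs (m, m+1) with m of the given parity,
        ascending; accepted swaps exchange the rung assignment only."""
        M = self.ladder.n_replicas
        if M < 2:
            if log is not None:
                log.record_snapshot(self.step_count, self.param_of_replica)
            return
        comps, _ = self.model.energy_components(self.X)
        betas = self.ladder.betas
        beta0 = self.ladder.beta_0
        replica_at = np.empty(M, int)
        replica_at[self.param_of_replica] = np.arange(M)
        for m in range(parity, M - 1, 2):
            a, b = replica_at[m], replica_at[m + 1]
            delta = _grouped_delta(
                betas[m], betas[m + 1], beta0, self.model.exponents,
                comps[a], comps[b],
            )
            acc = metropolis_accept(delta, self.controller_rng)
            if acc:
                self.param_of_replica[a] = m + 1
                self.param_of_replica[b] = m
                replica_at[m], replica_at[m + 1] = b, a
            if log is not None:
                log.record_attempt(self.step_count, m, delta, acc)
        if log is not None:
            log.record_snapshot(self.step_count, self.param_of_replica)

    # -- full runs ---------------------------------------------------------

    def run(self, total_steps: int, exchange_interval: int = 1000,
            save_interval: int | None = None,
            log: ExchangeLog | None = None) -> tuple[Trajectory, ExchangeLog]:
        """Alternate propagation blocks with neighbor-exchange sweeps.

        Frames are saved every ``save_interval`` steps (default: at each
        exchange boundary), before the exchange attempt at that step, so
        each frame carries the rung under which it was just propagated.
        """
        if exchange_interval < 1:
            raise ModelError("exchange_interval must be >= 1")
        save_interval = save_interval or exchange_interval
        if save_interval % exchange_interval and exchange_interval % save_interval:
            raise ModelError("save_interval must divide or be a multiple of exchange_interval")
        if log is None:
            log = ExchangeLog(n_params=self.ladder.n_replicas)
        frames_steps, frames_x, frames_map = [], [], []
        frames_comp, frames_evv, frames_E = [], [], []
        parity = 0
        done = 0
        next_save = save_interval
        lam_all = self.ladder.lambdas

        def save_frame() -> None:
            comps, evv = self.model.energy_components(self.X)
            lam = lam_all[self.param_of_replica]
            E = np.sum(comps * lam[:, None] ** self.model.exponents, axis=-1) + evv
            frames_steps.append(self.step_count)
            frames_x.append(self.X.copy())
            frames_map.append(self.param_of_replica.copy())
            frames_comp.append(comps)
            frames_evv.append(evv)
            frames_E.append(E)

        while done < total_steps:
            block = min(exchange_interval, total_steps - done)
            inner = 0
            while inner < block:
                sub = min(block - inner, next_save - (done + inner))
                self.propagate_block(sub)
                inner += sub
                if done + inner == next_save:
                    save_frame()
                    next_save += save_interval
            done += block
            if done < total_steps or block == exchange_interval:
                self.exchange_sweep(parity, log)
                parity = 1 - parity if self.ladder.n_replicas > 2 else 0
        M = self.ladder.n_replicas
        n, d = self.model.n_atoms, self.model.ndim
        ne = self.model.exponents.size
        traj = Trajectory(
            steps=np.asarray(frames_steps, int),
            coords=np.asarray(frames_x).reshape(-1, M, n, d),
            param_index=np.asarray(frames_map, int).reshape(-1, M),
            components=np.asarray(frames_comp).reshape(-1, M, ne),
            evv=np.asarray(frames_evv).reshape(-1, M),
            scaled_energy=np.asarray(frames_E).reshape(-1, M),
            exponents=self.model.exponents.copy(),
            betas=self.ladder.betas.copy(),
            beta_0=self.ladder.beta_0,
        )
        return traj, log


def propagate(system, sel: SoluteSelection, x: np.ndarray, n_steps: int,
              beta_m: float = 1.0, beta_0: float = 1.0, mode: str = "langevin",
              seed: int = 0, sample_interval: int | None = None, **kwargs):
    """Advance a single configuration under the scaled potential at the
    bath temperature beta_0 with scaling parameter beta_m.

    Returns the final coordinates, or — when ``sample_interval`` is given
    — an array of configurations saved every that many steps/sweeps.
    """
    if beta_m <= 0 or beta_0 <= 0:
        raise ModelError("inverse temperatures must be positive")
    ladder = ParameterLadder(np.array([beta_0]), beta_0)
    sampler = GRESTSampler(system, sel, ladder, mode=mode, seed=seed,
                           x0=np.asarray(x, float)[None], **kwargs)
    sampler.lambda_override = np.array([beta_m / beta_0])
    if sample_interval is None:
        sampler.propagate_block(n_steps)
        return sampler.X[0].copy()
    frames = []
    for _ in range(n_steps // sample_interval):
        sampler.propagate_block(sample_interval)
        frames.append(sampler.X[0].copy())
    return np.asarray(frames)


def run_grest(system, sel: SoluteSelection, ladder: ParameterLadder,
              total_steps: int, exchange_interval: int = 1000, seed: int = 0,
              mode: str = "langevin", save_interval: int | None = None,
              x0: np.ndarray | None = None, **kwargs) -> tuple[Trajectory, ExchangeLog]:
    """One-call gREST run: build the sampler, alternate propagation and
    exchange, and return the trajectory plus the exchange log."""
    if ladder.n_replicas < 1:
        raise ModelError("ladder must hold at least one rung")
    sampler = GRESTSampler(system, sel, ladder, mode=mode, seed=seed, x0=x0, **kwargs)
    return sampler.run(total_steps, exchange_interval, save_interval)


# ---------------------------------------------------------------------------
# ladder optimization


@dataclass
class LadderOptimizationResult:
    ladder: ParameterLadder       # best ladder seen (smallest worst-pair deviation)
    converged: bool
    rounds: int
    acceptance_history: list      # per-round per-pair acceptance arrays
    temperature_history: list     # per-round solute-temperature arrays
    best_acceptance: np.ndarray | None = None


def optimize_ladder(system, sel: SoluteSelection, n_replicas: int,
                    target_acceptance: float = 0.3, tolerance: float = 0.05,
                    max_rounds: int = 12, seed: int = 0, beta_0: float = 1.0,
                    t_max_factor: float = 5.0, trial_attempts_per_pair: int = 200,
                    trial_exchange_interval: int = 50,
                    equilibration_steps: int = 2000, mode: str = "langevin",
                    x0: np.ndarray | None = None,
                    **sampler_kwargs) -> LadderOptimizationResult:
    """Tune the rung spacing so every neighbor pair exchanges at about the
    target acceptance.

    Starting from a ladder geometric in solute temperature, each round
    runs a short trial, measures the per-pair acceptance p_m, and rescales
    the log-temperature gaps multiplicatively:

        ln(T_{m+1}/T_m) <- ln(T_{m+1}/T_m) * (ln(target) / ln(p_m))**damping

    (p_m clipped away from 0 and 1, the update factor clamped for
    stability; damping < 1 suppresses oscillation driven by the trial's
    own sampling noise). Rounds are warm-started from the previous
    round's replica coordinates. beta_1 = beta_0 is never modified.
    Returns the best ladder seen — the one whose measured worst-pair
    deviation from the target was smallest — with a convergence flag;
    non-convergence raises a warning, not an error.
    """
    if n_replicas < 2:
        raise ModelError("ladder optimization needs at least two replicas")
    if not 0.0 < target_acceptance < 1.0:
        raise ModelError("target acceptance must be in (0, 1)")
    damping = 0.6
    ladder = ParameterLadder.geometric(n_replicas, beta_0, t_max_factor)
    ss = np.random.SeedSequence(seed)
    round_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max_rounds)]
    # each pair is attempted every other sweep (even/odd alternation)
    n_sweeps = 2 * trial_attempts_per_pair
    trial_steps = n_sweeps * trial_exchange_interval
    history, temps_hist = [], []
    best = (np.inf, ladder, None)
    converged = False
    rounds = 0
    x_warm = x0
    for r in range(max_rounds):
        rounds = r + 1
        sampler = GRESTSampler(system, sel, ladder, mode=mode,
                               seed=round_seeds[r], x0=x_warm, **sampler_kwargs)
        if equilibration_steps:
            sampler.propagate_block(equilibration_steps)
        _, log = sampler.run(trial_steps, trial_exchange_interval)
        x_warm = sampler.X.copy()
        p = log.acceptance_ratios()
        history.append(p)
        temps_hist.append(ladder.temperatures.copy())
        dev = float(np.max(np.abs(p - target_acceptance)))
        if dev < best[0]:
            best = (dev, ladder, p)
        if dev <= tolerance:
            converged = True
            break
        p_c = np.clip(p, 0.005, 0.995)
        factors = np.clip(
            (np.log(target_acceptance) / np.log(p_c)) ** damping, 0.45, 2.2
        )
        temps = ladder.temperatures
        gaps = np.diff(np.log(temps)) * factors
        new_temps = temps[0] * np.exp(np.concatenate([[0.0], np.cumsum(gaps)]))
        ladder = ladder.with_temperatures(new_temps)
    if not converged:
        warnings.warn(
            f"ladder optimization did not converge in {max_rounds} rounds "
            f"(best worst-pair deviation {best[0]:.3f})",
            RuntimeWarning,
        )
    return LadderOptimizationResult(
        ladder=best[1], converged=converged, rounds=rounds,
        acceptance_history=history, temperature_history=temps_hist,
        best_acceptance=best[2],
    )
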