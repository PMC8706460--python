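"""Synthetic systems with independent oracles.

Three fixture families make the sampler testable without external data:

* harmonic baths — independent 1D oscillators whose partition function,
  positional moments and pairwise exchange-acceptance integrals are all
  available in closed form or by deterministic quadrature;
* the mini-loop — a bead chain whose flexible "loop" segment carries one
  bistable dihedral (wells near 0 and pi, an analogue of cis/trans
  peptide-bond isomers) grafted onto a positionally restrained
  "framework", emulating a flexible antibody CDR loop on a rigid domain;
* discrete systems — finite state spaces with explicit energy buckets,
  for which the full extended-ensemble transition matrix of the
  sampler + exchange chain can be enumerated exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

from .model import (
    EnergyDecomposition,
    SoluteSelection,
    ToySystem,
    dihedral_angles,
)
from .sampling import ParameterLadder, metropolis_probability

__all__ = [
    "HarmonicBath",
    "make_harmonic_bath",
    "pair_acceptance_gamma",
    "spacing_for_acceptance",
    "MiniLoop",
    "make_mini_loop",
    "count_well_transitions",
    "DiscreteSystem",
    "make_discrete",
    "DiscreteGREST",
]


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# harmonic baths


class HarmonicBath:
    """f_solute + f_solvent independent 1D harmonic coordinates.

    Coordinate i has energy k_i x_i^2 / 2; the first ``f_solute``
    coordinates are the designated solute. All solute energy is
    solute-solute (each term is one-body, so k = l and the tempering
    exponent is 1); there are no cross terms, and the solvent bucket
    cancels from the exchange criterion exactly.
    """

    def __init__(self, stiff_solute: np.ndarray, stiff_solvent: np.ndarray):
        self.stiff_solute = np.asarray(stiff_solute, float).ravel()
        self.stiff_solvent = np.asarray(stiff_solvent, float).ravel()
        if np.any(self.stiff_solute <= 0) or np.any(self.stiff_solvent <= 0):
            raise FixtureError("stiffnesses must be positive")
        self.stiffness = np.concatenate([self.stiff_solute, self.stiff_solvent])
        self.positions = np.zeros((self.stiffness.size, 1))
        self.masses = np.ones(self.stiffness.size)

    @property
    def f_solute(self) -> int:
        return self.stiff_solute.size

    @property
    def f_solvent(self) -> int:
        return self.stiff_solvent.size

    @property
    def n_atoms(self) -> int:
        return self.stiffness.size

    @property
    def ndim(self) -> int:
        return 1

    def compile(self, sel: SoluteSelection) -> "ScaledBathModel":
        return ScaledBathModel(self, sel)


class ScaledBathModel:
    """Compiled (bath, selection) pair; selected coordinates scale with
    exponent 1, unselected ones are untempered solvent."""

    independent_dofs = True

    def __init__(self, bath: HarmonicBath, sel: SoluteSelection):
        sel.validate(bath)
        self.system = bath
        self.selection = sel
        self.exponents = np.array([1.0])
        mask = np.zeros(bath.n_atoms, bool)
        mask[list(sel.atom_indices)] = True
        self.solute_mask = mask

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms

    @property
    def ndim(self) -> int:
        return 1

    @property
    def masses(self) -> np.ndarray:
        return self.system.masses

    def _site_energies(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.system.stiffness * np.sum(np.asarray(x, float) ** 2, axis=-1)

    def energy_components(self, x: np.ndarray):
        e = self._site_energies(x)
        comps = np.sum(e[..., self.solute_mask], axis=-1)[..., None]
        evv = np.sum(e[..., ~self.solute_mask], axis=-1)
        return comps, evv

    def scaled_energy(self, x: np.ndarray, lam) -> np.ndarray:
        comps, evv = self.energy_components(x)
        return np.asarray(lam, float) * comps[..., 0] + evv

    def per_dof_scaled_energy(self, x: np.ndarray, lam) -> np.ndarray:
        e = self._site_energies(x)
        w = np.where(self.solute_mask, np.asarray(lam, float)[..., None], 1.0)
        return w * e

    def scaled_forces(self, x: np.ndarray, lam) -> np.ndarray:
        x = np.asarray(x, float)
        w = np.where(self.solute_mask, np.asarray(lam, float)[..., None], 1.0)
        return -(w * self.system.stiffness)[..., None] * x

    def decompose(self, x: np.ndarray) -> EnergyDecomposition:
        comps, evv = self.energy_components(x)
        return EnergyDecomposition(E_uu=float(comps[..., 0]), uv_terms=[], E_vv=float(evv))


def make_harmonic_bath(f_solute: int, f_solvent: int, k_solute: float = 1.0,
                       k_solvent: float = 1.0) -> tuple[HarmonicBath, SoluteSelection]:
    """Bath with the first ``f_solute`` coordinates selected as solute."""
    if f_solute < 1 or f_solvent < 0:
        raise FixtureError("f_solute must be >= 1 and f_solvent >= 0")
    bath = HarmonicBath(np.full(f_solute, k_solute), np.full(f_solvent, k_solvent))
    sel = SoluteSelection(range(f_solute), "all")
    return bath, sel


def pair_acceptance_gamma(f: int, beta_cold: float, beta_hot: float) -> float:
    """Mean Metropolis swap acceptance between two replicas whose relevant
    energies are Gamma(f/2) distributed at inverse temperatures beta_cold
    > beta_hot (deterministic quadrature, no simulation).

    For a harmonic bath this is exact: the tempered energy of f
    quadratic degrees of freedom at inverse temperature beta is
    Gamma(f/2, 1/beta). Used both for T-REMD (f = all degrees of
    freedom) and for solute tempering (f = solute degrees of freedom,
    the solvent cancels).
    """
    if beta_hot >= beta_cold:
        raise FixtureError("expected beta_cold > beta_hot")
    a = f / 2.0
    c_abs = beta_cold - beta_hot
    # accept with prob 1 when the cold replica's energy exceeds the hot
    # one's; otherwise exp(-|c| (E_hot - E_cold)).
    log_ratio_term = a * math.log(beta_cold / beta_hot)

    def integrand(e2: float) -> float:
        p2 = stats.gamma.pdf(e2, a, scale=1.0 / beta_hot)
        if p2 == 0.0:
            return 0.0
        always = special.gammaincc(a, beta_cold * e2)
        log_partial = log_ratio_term - c_abs * e2
        partial = 0.0
        if log_partial > -700.0:
            partial = math.exp(min(log_partial, 700.0)) * special.gammainc(a, beta_hot * e2)
        return p2 * (always + partial)

    mean2 = a / beta_hot
    sd2 = math.sqrt(a) / beta_hot
    lo, hi = max(0.0, mean2 - 14 * sd2), mean2 + 14 * sd2
    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(val)


def spacing_for_acceptance(f: int, target: float, beta_cold: float = 1.0) -> float:
    """Log temperature-ratio ln(T_hot/T_cold) at which the pair acceptance
    equals ``target`` (root-found on the quadrature oracle)."""

    def g(log_r: float) -> float:
        return pair_acceptance_gamma(f, beta_cold, beta_cold / math.exp(log_r)) - target

    return float(optimize.brentq(g, 1e-6, 10.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# mini-loop bead chain


@dataclass
class MiniLoop:
    """A flexible loop on a restrained framework, with one bistable
    dihedral emulating cis/trans isomerization.

    ``start`` sits in the cis well (the emulated modeling error);
    ``reference`` sits in the trans well. The solute selection covers the
    loop beads; its categories default to all three tempered classes.
    """

    system: ToySystem
    selection: SoluteSelection
    start: np.ndarray
    reference: np.ndarray
    loop_atoms: np.ndarray
    framework_atoms: np.ndarray
    bistable_dihedral: int          # row index into system.dihedrals
    barrier_height: float
    seed: int

    def selection_with(self, categories) -> SoluteSelection:
        return SoluteSelection(self.loop_atoms, categories)

    def bistable_angles(self, coords: np.ndarray) -> np.ndarray:
        """The bistable dihedral angle for one frame or a batch."""
        quad = self.system.dihedrals[self.bistable_dihedral][None, :]
        return dihedral_angles(coords, quad)[..., 0]


def make_mini_loop(n_framework: int = 12, n_loop: int = 16,
                   barrier_height: float = 14.0, seed: int = 0,
                   tilt: float = 8.0, bond_k: float = 100.0,
                   angle_k: float = 20.0, generic_dihedral_k: float = 1.0,
                   lj_eps: float = 3.0, lj_sigma: float = 1.2,
                   charge: float = 1.0, restraint_k: float = 100.0,
                   gap_angle: float = 3.0, corral_k: float = 25.0,
                   corral_radius: float | None = None,
                   categories="all", relax: bool = True) -> MiniLoop:
    """Build the default mini-loop fixture.

    The topology is a macrocycle, like a CDR loop anchored at both ends
    to a rigid domain: framework beads sit on a circular arc (each
    harmonically restrained to its scaffold position) and the loop beads
    bridge the remaining gap with slack, so the loop stays immersed in
    its framework environment at every rung — its cross interactions are
    tethered and never simply evaporate at high solute temperature.
    Consecutive beads around the cycle are bonded (r0 = 1) and carry
    harmonic angles; quadruples in the loop region carry soft
    extended-state dihedrals except the central all-loop quadruple, which
    instead carries the bistable pair

        U(phi) = (barrier/2) (1 + cos(2 phi - pi)) + (tilt/2) (1 + cos phi)

    with wells near phi = 0 (cis) and phi = pi (trans, lower by ~tilt —
    the analogue of the favored trans peptide bond). Beads interact by
    Lennard-Jones and alternating +/- charges; 1-2 and 1-3 pairs are
    excluded, 1-4 pairs are at full strength.
    """
    if n_loop < 4:
        raise FixtureError("n_loop must be >= 4 (the bistable dihedral needs 4 loop beads)")
    if n_framework < 6:
        raise FixtureError("n_framework must be >= 6")
    if barrier_height <= 0:
        raise FixtureError("barrier height must be positive")
    n = n_framework + n_loop
    bond_r0 = 1.0
    theta0 = 1.91  # ~109.5 degrees, keeps angles well away from collinear
    rng = np.random.default_rng(seed)

    # framework arc: n_framework beads at unit spacing on a circle leaving
    # a gap of gap_angle radians; the loop spans the gap chord with
    # n_loop + 1 bonds, slack = bonds / chord.
    radius = (n_framework - 1) * bond_r0 / (2.0 * math.pi - gap_angle)
    fw_angles = gap_angle / 2.0 + np.arange(n_framework) * (
        (2.0 * math.pi - gap_angle) / (n_framework - 1)
    )
    scaffold_fw = radius * np.stack(
        [np.cos(fw_angles), np.sin(fw_angles), np.zeros(n_framework)], axis=1
    )
    chord = float(np.linalg.norm(scaffold_fw[0] - scaffold_fw[-1]))
    if (n_loop + 1) * bond_r0 < 1.05 * chord:
        raise FixtureError(
            f"loop too short to bridge the framework gap (chord {chord:.2f}, "
            f"{n_loop + 1} bonds); increase n_loop or shrink gap_angle"
        )

    # initial loop path: circular arc bulging out of the framework plane
    p_start, p_end = scaffold_fw[-1], scaffold_fw[0]
    u = (p_end - p_start) / chord
    target_len = 0.97 * (n_loop + 1) * bond_r0

    def arc_defect(alpha: float) -> float:
        return alpha / math.sin(alpha) - target_len / chord

    alpha = optimize.brentq(arc_defect, 1e-6, math.pi - 1e-6)
    rho = chord / (2.0 * math.sin(alpha))
    center = 0.5 * (p_start + p_end) - np.array([0.0, 0.0, rho * math.cos(alpha)])
    ts = np.linspace(-alpha, alpha, n_loop + 2)[1:-1]
    loop0 = center + rho * (
        np.sin(ts)[:, None] * u + np.cos(ts)[:, None] * np.array([0.0, 0.0, 1.0])
    )
    scaffold = np.vstack([scaffold_fw, loop0])

    loop_atoms = np.arange(n_framework, n)
    framework_atoms = np.arange(n_framework)
    bonds = [[i, i + 1] for i in range(n - 1)] + [[n - 1, 0]]
    angles = [[i, (i + 1) % n, (i + 2) % n] for i in range(n)]
    # framework triples rest at the arc's own interior angle; loop and
    # junction triples at the tetrahedral-like chain angle
    arc_step = (2.0 * math.pi - gap_angle) / (n_framework - 1)
    theta_fw = math.pi - arc_step
    angle_theta0 = np.array(
        [theta_fw if max(t) < n_framework else theta0 for t in angles]
    )

    # dihedrals on the loop region and its junctions; the bistable pair
    # sits on the central all-loop quadruple
    quad_starts = list(range(n_framework - 3, n))
    bistable_start = n_framework + (n_loop - 4) // 2
    dihedrals, K, mult, delta = [], [], [], []
    bistable_row = None
    for i in quad_starts:
        q = [i % n, (i + 1) % n, (i + 2) % n, (i + 3) % n]
        if i == bistable_start:
            bistable_row = len(dihedrals)
            dihedrals.append(q)
            K.append(barrier_height / 2.0)
            mult.append(2)
            delta.append(math.pi)
            dihedrals.append(q)
            K.append(tilt / 2.0)
            mult.append(1)
            delta.append(0.0)
        else:
            dihedrals.append(q)
            K.append(generic_dihedral_k)
            mult.append(1)
            delta.append(0.0)

    system = ToySystem(
        positions=scaffold.copy(),
        masses=np.ones(n),
        charges=charge * np.where(np.arange(n) % 2 == 0, 1.0, -1.0),
        lj_eps=np.full(n, lj_eps),
        lj_sigma=np.full(n, lj_sigma),
        bonds=np.asarray(bonds),
        bond_k=np.full(len(bonds), bond_k),
        bond_r0=np.full(len(bonds), bond_r0),
        angles=np.asarray(angles),
        angle_k=np.full(len(angles), angle_k),
        angle_theta0=angle_theta0,
        dihedrals=np.asarray(dihedrals),
        dihedral_K=np.asarray(K),
        dihedral_n=np.asarray(mult),
        dihedral_delta=np.asarray(delta),
        restraint_atoms=framework_atoms,
        restraint_k=np.full(n_framework, restraint_k),
        restraint_x0=scaffold_fw.copy(),
        # flat-bottom well around the gap region: the untempered stand-in
        # for solvent crowding that keeps even a hot loop immersed in its
        # environment instead of evaporating into vacuum
        corral_atoms=loop_atoms,
        corral_k=np.full(n_loop, corral_k),
        corral_radius=np.full(
            n_loop,
            corral_radius if corral_radius is not None
            else max(1.8, 0.73 * lj_sigma * n_loop ** (1.0 / 3.0)),
        ),
        corral_x0=np.tile(0.5 * (p_start + p_end), (n_loop, 1)),
    )
    sel = SoluteSelection(loop_atoms, categories)

    jitter = 0.01
    bq = np.asarray(dihedrals[bistable_row])
    x_trans = scaffold + jitter * rng.standard_normal((n, 3))
    x_cis = scaffold + jitter * rng.standard_normal((n, 3))
    if relax:
        reference = _relax(system, x_trans, bias=(bq, math.pi))
        start = _relax(system, x_cis, bias=(bq, 0.0))
    else:
        reference, start = x_trans, x_cis

    ml = MiniLoop(
        system=system, selection=sel, start=start, reference=reference,
        loop_atoms=loop_atoms, framework_atoms=framework_atoms,
        bistable_dihedral=bistable_row, barrier_height=barrier_height, seed=seed,
    )
    if relax:
        phi_ref = float(ml.bistable_angles(reference))
        phi_start = float(ml.bistable_angles(start))
        if not (abs(abs(phi_ref) - math.pi) < 1.0 and abs(phi_start) < 1.0):
            raise FixtureError(
                "mini-loop relaxation left a dihedral outside its well "
                f"(start phi={phi_start:.3f}, reference phi={phi_ref:.3f}); "
                "parameters are geometrically infeasible"
            )
    d = np.linalg.norm(start[:, None] - start[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 0.3 * lj_sigma:
        raise FixtureError(
            f"overlapping beads in the start structure (min distance {d.min():.3f}); "
            "parameters are geometrically infeasible"
        )
    system.positions = start.copy()
    return ml


def _relax(system: ToySystem, x0: np.ndarray, bias=None,
           maxiter: int = 2000) -> np.ndarray:
    """Local minimization of the unscaled potential; an optional dihedral
    bias (quad, phi_target) steers the structure into the requested well
    before an unbiased polish."""
    from .model import compile_model

    model = compile_model(system, SoluteSelection([0], "all"))
    n = system.n_atoms

    def stage(x_in: np.ndarray, bias_k: float) -> np.ndarray:
        def fun(flat):
            x = flat.reshape(n, 3)
            e = float(model.scaled_energy(x, 1.0))
            g = -model.scaled_forces(x, 1.0)
            if bias is not None and bias_k:
                quad, phi_t = bias
                phi = float(dihedral_angles(x, quad[None, :])[0])
                e += bias_k * (1.0 - math.cos(phi - phi_t))
                dU = bias_k * math.sin(phi - phi_t)
                gphi = _dihedral_gradient(x, quad)
                g += dU * gphi
            return e, g.ravel()

        res = optimize.minimize(fun, x_in.ravel(), jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter, "gtol": 1e-8})
        return res.x.reshape(n, 3)

    x = stage(x0, 25.0) if bias is not None else x0
    return stage(x, 0.0)


def _dihedral_gradient(x: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """d(phi)/dx for one dihedral quadruple, zero elsewhere."""
    i0, i1, i2, i3 = (int(i) for i in quad)
    b1 = x[i1] - x[i0]
    b2 = x[i2] - x[i1]
    b3 = x[i3] - x[i2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    tA = -(nb2 / (n1 @ n1)) * n1
    tD = (nb2 / (n2 @ n2)) * n2
    s = float(b1 @ b2) / nb2**2
    t = float(b3 @ b2) / nb2**2
    g = np.zeros_like(x)
    g[i0] = tA
    g[i1] = -(1.0 + s) * tA + t * tD
    g[i2] = s * tA - (1.0 + t) * tD
    g[i3] = tD
    return g


def count_well_transitions(phi: np.ndarray, core_halfwidth: float = 0.6) -> int:
    """Count cis <-> trans flips of a dihedral time series.

    A flip is registered only when the angle enters the *core* of the
    other well (|phi| < core for cis, |pi - |phi|| < core for trans), so
    barrier-top jitter is not counted.
    """
    phi = np.asarray(phi, float).ravel()
    state = 0  # 0 unknown, 1 cis, 2 trans
    flips = 0
    for p in phi:
        if abs(p) < core_halfwidth:
            here = 1
        elif abs(abs(p) - math.pi) < core_halfwidth:
            here = 2
        else:
            continue
        if state and here != state:
            flips += 1
        state = here
    return flips


# ---------------------------------------------------------------------------
# discrete systems


@dataclass
class DiscreteSystem:
    """Finite state space with explicit per-state energy buckets.

    ``uv`` holds (energies, k, l) with energies of shape (n_states,).
    """

    E_uu: np.ndarray
    uv: list
    E_vv: np.ndarray

    def __post_init__(self) -> None:
        self.E_uu = np.asarray(self.E_uu, float).ravel()
        self.E_vv = np.asarray(self.E_vv, float).ravel()
        if self.E_uu.size != self.E_vv.size or self.E_uu.size < 2:
            raise FixtureError("need matching E_uu/E_vv arrays over >= 2 states")
        self.uv = [(np.asarray(e, float).ravel(), int(k), int(l)) for e, k, l in self.uv]
        for e, k, l in self.uv:
            if e.size != self.n_states or not 0 < k < l:
                raise FixtureError("uv terms must have 0 < k < l and one energy per state")

    @property
    def n_states(self) -> int:
        return self.E_uu.size

    @property
    def exponents(self) -> np.ndarray:
        exps = sorted({1.0} | {k / l for _, k, l in self.uv})
        return np.array(exps)

    def components(self) -> np.ndarray:
        """(n_states, n_exponents) grouped energies; E_vv excluded."""
        exps = self.exponents
        comp = np.zeros((self.n_states, exps.size))
        comp[:, np.searchsorted(exps, 1.0)] += self.E_uu
        for e, k, l in self.uv:
            comp[:, np.searchsorted(exps, k / l)] += e
        return comp

    def scaled_energies(self, beta_m: float, beta_0: float) -> np.ndarray:
        """E_m for every state at scaling parameter beta_m."""
        lam = beta_m / beta_0
        return self.components() @ (lam ** self.exponents) + self.E_vv

    def decompose(self, state: int) -> EnergyDecomposition:
        return EnergyDecomposition(
            E_uu=float(self.E_uu[state]),
            uv_terms=[(float(e[state]), k, l) for e, k, l in self.uv],
            E_vv=float(self.E_vv[state]),
        )


def make_discrete(n_states: int, energies=None, uv_terms=None, evv=None,
                  seed: int = 0) -> DiscreteSystem:
    """A discrete fixture; with no explicit energies, draws modest random
    ones reproducibly from the seed."""
    if n_states < 2:
        raise FixtureError("n_states must be >= 2")
    rng = np.random.default_rng(seed)
    if energies is None:
        energies = rng.uniform(0.0, 3.0, n_states)
    if uv_terms is None:
        uv_terms = [(rng.uniform(0.0, 2.0, n_states), 1, 2)]
    if evv is None:
        evv = rng.uniform(0.0, 5.0, n_states)
    return DiscreteSystem(np.asarray(energies), list(uv_terms), np.asarray(evv))


class DiscreteGREST:
    """Exact extended-ensemble chain for a discrete system under the
    propagate + exchange dynamics.

    One *round* is: a Metropolis sweep (each replica proposes a uniform
    different state against its scaled Boltzmann weight), an even-pair
    exchange sweep, another Metropolis sweep, and an odd-pair exchange
    sweep. Both the exact round transition matrix and a step-by-step
    simulator of the same chain are exposed.
    """

    def __init__(self, system: DiscreteSystem, ladder: ParameterLadder):
        self.system = system
        self.ladder = ladder
        S, M = system.n_states, ladder.n_replicas
        self.S, self.M = S, M
        self.perms = list(itertools.permutations(range(M)))
        self.states = [
            (cfg, p) for cfg in itertools.product(range(S), repeat=M)
            for p in range(len(self.perms))
        ]
        self.index = {st: i for i, st in enumerate(self.states)}
        # per-rung scaled state energies and single-replica move kernels
        self.E_m = np.stack(
            [system.scaled_energies(b, ladder.beta_0) for b in ladder.betas]
        )  # (M, S)
        self.move_kernels = np.stack([self._metropolis_kernel(m) for m in range(M)])

    def _metropolis_kernel(self, m: int) -> np.ndarray:
        """S x S one-sweep kernel: uniform proposal + Metropolis at rung m."""
        S = self.S
        beta0 = self.ladder.beta_0
        E = self.E_m[m]
        P = np.zeros((S, S))
        for s in range(S):
            for t in range(S):
                if t == s:
                    continue
                P[s, t] = metropolis_probability(beta0 * (E[t] - E[s])) / (S - 1)
            P[s, s] = 1.0 - P[s].sum()
        return P

    # -- exact matrices ----------------------------------------------------

    def propagation_matrix(self) -> np.ndarray:
        """Extended-ensemble kernel of one Metropolis sweep of all replicas."""
        n = len(self.states)
        P = np.zeros((n, n))
        for i, (cfg, p) in enumerate(self.states):
            perm = self.perms[p]
            per_rep = [self.move_kernels[perm[a]][cfg[a]] for a in range(self.M)]
            for new_cfg in itertools.product(range(self.S), repeat=self.M):
                prob = 1.0
                for a in range(self.M):
                    prob *= per_rep[a][new_cfg[a]]
                if prob:
                    P[i, self.index[(new_cfg, p)]] += prob
        return P

    def exchange_matrix(self, parity: int) -> np.ndarray:
        """Extended-ensemble kernel of one even- or odd-pair exchange sweep."""
        n = len(self.states)
        comp = self.system.components()
        exps = self.system.exponents
        betas = self.ladder.betas
        beta0 = self.ladder.beta_0
        P = np.zeros((n, n))
        for i, (cfg, p) in enumerate(self.states):
            perm = list(self.perms[p])
            replica_at = {perm[a]: a for a in range(self.M)}
            # pairs in a sweep are disjoint: accumulate the product measure
            outcomes = [(perm, 1.0)]
            for m in range(parity, self.M - 1, 2):
                a, b = replica_at[m], replica_at[m + 1]
                w = beta0 ** (1.0 - exps) * (betas[m + 1] ** exps - betas[m] ** exps)
                delta = float(np.dot(w, comp[cfg[a]] - comp[cfg[b]]))
                pacc = metropolis_probability(delta)
                new_outcomes = []
                for q, prob in outcomes:
                    if pacc > 0.0:
                        q2 = list(q)
                        q2[a], q2[b] = m + 1, m
                        new_outcomes.append((q2, prob * pacc))
                    if pacc < 1.0:
                        new_outcomes.append((q, prob * (1.0 - pacc)))
                outcomes = new_outcomes
            for q, prob in outcomes:
                P[i, self.index[(cfg, self.perms.index(tuple(q)))]] += prob
        return P

    def round_matrix(self) -> np.ndarray:
        Pp = self.propagation_matrix()
        return Pp @ self.exchange_matrix(0) @ Pp @ self.exchange_matrix(1)

    def stationary_weights(self) -> np.ndarray:
        """Target stationary law: product of scaled Boltzmann weights over
        replicas (uniform over rung assignments), normalized."""
        beta0 = self.ladder.beta_0
        w = np.empty(len(self.states))
        for i, (cfg, p) in enumerate(self.states):
            perm = self.perms[p]
            logw = -beta0 * sum(self.E_m[perm[a], cfg[a]] for a in range(self.M))
            w[i] = logw
        w = np.exp(w - w.max())
        return w / w.sum()

    def stationary_from_eigen(self) -> np.ndarray:
        """Stationary law of the exact round kernel by eigen-analysis."""
        T = self.round_matrix()
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()

    # -- simulation of the same chain ---------------------------------------

    def simulate(self, n_rounds: int, seed: int = 0) -> np.ndarray:
        """Run the chain and return empirical extended-state frequencies."""
        rng = np.random.default_rng(seed)
        S, M = self.S, self.M
        cfg = [0] * M
        perm = list(range(M))  # replica -> rung
        counts = np.zeros(len(self.states))
        beta0 = self.ladder.beta_0
        comp = self.system.components()
        exps = self.system.exponents
        betas = self.ladder.betas
        pair_w = {
            m: beta0 ** (1.0 - exps) * (betas[m + 1] ** exps - betas[m] ** exps)
            for m in range(M - 1)
        }
        # batched randomness: per round, M proposals+uniforms per sweep x2
        for start in range(0, n_rounds, 20000):
            chunk = min(20000, n_rounds - start)
            props = rng.integers(0, S - 1, size=(chunk, 2, M))
            umove = rng.random(size=(chunk, 2, M))
            uex = rng.random(size=(chunk, 2, max(M - 1, 1)))
            for r in range(chunk):
                for half in range(2):
                    for a in range(M):
                        t = props[r, half, a]
                        if t >= cfg[a]:
                            t += 1
                        dE = self.E_m[perm[a], t] - self.E_m[perm[a], cfg[a]]
                        if dE <= 0 or umove[r, half, a] <= math.exp(-beta0 * dE):
                            cfg[a] = int(t)
                    replica_at = {perm[a]: a for a in range(M)}
                    for j, m in enumerate(range(half, M - 1, 2)):
                        a, b = replica_at[m], replica_at[m + 1]
                        delta = float(np.dot(pair_w[m], comp[cfg[a]] - comp[cfg[b]]))
                        if delta <= 0 or uex[r, half, j] <= math.exp(-delta):
                            perm[a], perm[b] = m + 1, m
                            replica_at[m], replica_at[m + 1] = b, a
                counts[self.index[(tuple(cfg), self.perms.index(tuple(perm)))]] += 1
        return counts / counts.sum()
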