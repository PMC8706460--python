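"""Toy molecular systems and the solute-tempering scaled potential.

A :class:`ToySystem` is a bead model in reduced units (k_B = 1, unit
charge/length/mass) with harmonic bonds and angles, cosine-series
dihedrals, Lorentz-Berthelot 12-6 Lennard-Jones and plain (non-periodic,
cutoff-free) Coulomb pairs, and optional harmonic positional restraints.

Solute tempering partitions every potential-energy term against a
:class:`SoluteSelection` — a set of "solute" atoms plus the term
categories (dihedral, vdW, electrostatic) that participate in tempering.
A term of a selected category with all ``l`` of its atoms inside the
solute is solute-solute (UU); with ``0 < k < l`` atoms inside it is a
solute-solvent cross term (UV) carrying the fractional exponent ``k/l``;
everything else — including bond, angle and restraint terms, which are
never tempered — is solvent-solvent (VV).

The replica with scaling parameter (solute inverse "temperature")
``beta_m`` at bath inverse temperature ``beta_0`` feels the potential

    E_m = (beta_m/beta_0) * E_uu
        + sum_i (beta_m/beta_0)**(k_i/l_i) * E_uv,i
        + E_vv

which reduces to the REST2 form when every cross exponent is 1/2 on a
two-body boundary, and to plain temperature scaling of the whole
potential when the solute is the entire system with all categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ToySystem",
    "SoluteSelection",
    "TermClass",
    "EnergyDecomposition",
    "classify_terms",
    "decompose_energy",
    "scaled_potential",
    "scaled_forces",
    "compile_model",
    "ScaledToyModel",
]

SCALABLE_CATEGORIES = frozenset({"dihedral", "vdw", "elec"})


# ---------------------------------------------------------------------------
# domain types


class ModelError(ValueError):
    """Invalid system, selection, or coordinates."""


@dataclass
class ToySystem:
    """A small bead system in reduced units.

    Parameters
    ----------
    positions : (N, 3) array
        Reference coordinates (reduced length units).
    masses, charges : (N,) arrays
    lj_eps, lj_sigma : (N,) arrays
        Per-atom Lennard-Jones well depth (>= 0) and diameter (> 0);
        pairs combine by Lorentz-Berthelot rules.
    bonds : (nb, 2) int array, with ``bond_k``/``bond_r0`` of shape (nb,)
        Harmonic bonds, U = 1/2 k (r - r0)^2.
    angles : (na, 3) int array, with ``angle_k``/``angle_theta0``
        Harmonic angles, U = 1/2 k (theta - theta0)^2.
    dihedrals : (nd, 4) int array, with ``dihedral_K``/``dihedral_n``/
        ``dihedral_delta``: cosine series U = K (1 + cos(n phi - delta)),
        phi in the IUPAC sign convention.
    exclusions : set of (i, j) pairs excluded from nonbonded evaluation.
        If None, the 1-2 and 1-3 pairs implied by the bond graph are used.
        1-4 pairs interact at full strength.
    restraint_atoms / restraint_k / restraint_x0 : optional positional
        restraints U = 1/2 k |x - x0|^2; never tempered (always VV).
    corral_atoms / corral_k / corral_radius / corral_x0 : optional
        flat-bottom spherical wells U = 1/2 k max(0, |x - x0| - R)^2,
        an untempered stand-in for solvent crowding; never tempered.
    """

    positions: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    lj_eps: np.ndarray
    lj_sigma: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    dihedral_K: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_n: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    dihedral_delta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exclusions: set | None = None
    restraint_atoms: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    restraint_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    restraint_x0: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    corral_atoms: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    corral_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    corral_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))
    corral_x0: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ModelError("positions must have shape (n_atoms, 3)")
        n = self.positions.shape[0]
        for name in ("masses", "charges", "lj_eps", "lj_sigma"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n,):
                raise ModelError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if np.any(self.masses <= 0):
            raise ModelError("masses must be positive")
        if np.any(self.lj_eps < 0):
            raise ModelError("lj_eps must be non-negative")
        if np.any(self.lj_sigma <= 0):
            raise ModelError("lj_sigma must be positive")
        for name, width in (("bonds", 2), ("angles", 3), ("dihedrals", 4)):
            idx = np.asarray(getattr(self, name), int).reshape(-1, width)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ModelError(f"{name} index out of range [0, {n})")
            for row in idx:
                if len(set(row.tolist())) != width:
                    raise ModelError(f"{name} entries must have distinct atoms")
            setattr(self, name, idx)
        self.bonds = self.bonds.reshape(-1, 2)
        for name in (
            "bond_k", "bond_r0", "angle_k", "angle_theta0",
            "dihedral_K", "dihedral_delta", "restraint_k",
            "corral_k", "corral_radius",
        ):
            setattr(self, name, np.asarray(getattr(self, name), float).ravel())
        self.dihedral_n = np.asarray(self.dihedral_n, int).ravel()
        self.restraint_atoms = np.asarray(self.restraint_atoms, int).ravel()
        self.restraint_x0 = np.asarray(self.restraint_x0, float).reshape(-1, 3)
        self.corral_atoms = np.asarray(self.corral_atoms, int).ravel()
        self.corral_x0 = np.asarray(self.corral_x0, float).reshape(-1, 3)
        if np.any(self.corral_radius < 0) or np.any(self.corral_k < 0):
            raise ModelError("corral radius and stiffness must be non-negative")
        implied = _topological_exclusions(n, self.bonds)
        if self.exclusions is None:
            self.exclusions = implied
        else:
            self.exclusions = {_canonical_pair(p) for p in self.exclusions}
            missing = implied - self.exclusions
            if missing:
                raise ModelError(
                    f"exclusions must contain all 1-2/1-3 pairs; missing {sorted(missing)}"
                )
        self._pairs = self._build_pair_list()

    # -- derived quantities ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return 3

    @property
    def nonbonded_pairs(self) -> np.ndarray:
        """(np, 2) array of non-excluded atom pairs, i < j, ascending."""
        return self._pairs

    def _build_pair_list(self) -> np.ndarray:
        n = self.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        keep = [k for k in range(iu.size) if (int(iu[k]), int(ju[k])) not in self.exclusions]
        return np.stack([iu[keep], ju[keep]], axis=1) if keep else np.zeros((0, 2), int)

    def pair_lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Lorentz-Berthelot (eps_ij, sigma_ij) over the nonbonded pair list."""
        i, j = self._pairs.T if self._pairs.size else (np.zeros(0, int),) * 2
        eps = np.sqrt(self.lj_eps[i] * self.lj_eps[j])
        sig = 0.5 * (self.lj_sigma[i] + self.lj_sigma[j])
        return eps, sig

    def pair_charges(self) -> np.ndarray:
        """q_i * q_j over the nonbonded pair list."""
        if not self._pairs.size:
            return np.zeros(0)
        i, j = self._pairs.T
        return self.charges[i] * self.charges[j]


def _canonical_pair(p: Iterable[int]) -> tuple[int, int]:
    a, b = sorted(int(x) for x in p)
    if a == b:
        raise ModelError("excluded pair must have distinct atoms")
    return a, b


def _topological_exclusions(n_atoms: int, bonds: np.ndarray) -> set:
    """1-2 and 1-3 pairs implied by the bond graph."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    out: set[tuple[int, int]] = set()
    for i, j in bonds:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
        out.add(_canonical_pair((i, j)))
    for center, nbrs in adj.items():
        for a in nbrs:
            for b in nbrs:
                if a < b:
                    out.add((a, b))
    return out


@dataclass(frozen=True)
class SoluteSelection:
    """Solute atom region plus the tempered term categories.

    ``categories`` is a non-empty subset of {"dihedral", "vdw", "elec"};
    "all" means exactly these three — bond, angle and restraint terms are
    never tempered.
    """

    atom_indices: frozenset
    categories: frozenset

    def __init__(self, atom_indices: Iterable[int], categories: Iterable[str] | str = "all"):
        if isinstance(categories, str):
            cats = SCALABLE_CATEGORIES if categories == "all" else frozenset({categories})
        else:
            cats = frozenset(categories)
        if not cats or not cats <= SCALABLE_CATEGORIES:
            raise ModelError(
                f"categories must be a non-empty subset of {sorted(SCALABLE_CATEGORIES)}"
            )
        object.__setattr__(self, "atom_indices", frozenset(int(i) for i in atom_indices))
        object.__setattr__(self, "categories", cats)

    def validate(self, system) -> None:
        n = system.n_atoms
        bad = [i for i in self.atom_indices if i < 0 or i >= n]
        if bad:
            raise ModelError(f"solute atom indices out of range [0, {n}): {sorted(bad)}")


@dataclass(frozen=True)
class TermClass:
    """Classification of one potential term against a solute selection."""

    term_id: str
    category: str
    k: int  # atoms of the term inside the solute region
    l: int  # total atoms the term involves
    bucket: str  # "UU" | "UV" | "VV"


@dataclass
class EnergyDecomposition:
    """Solute-solute / cross / solvent-solvent energy buckets.

    ``uv_terms`` holds (E_uv_i, k_i, l_i) triples; the scaled potential
    weights each by (beta_m/beta_0)**(k_i/l_i).
    """

    E_uu: float
    uv_terms: list
    E_vv: float

    @property
    def total(self) -> float:
        return self.E_uu + sum(e for e, _, _ in self.uv_terms) + self.E_vv


# ---------------------------------------------------------------------------
# term classification


def classify_terms(system: ToySystem, sel: SoluteSelection) -> list:
    """Assign every bonded term and non-excluded nonbonded pair a
    :class:`TermClass` (UU / UV / VV bucket with its k and l counts).

    Positional restraints are not classified: they are untempered by
    construction and always contribute to E_vv.
    """
    sel.validate(system)
    solute = sel.atom_indices
    out: list[TermClass] = []

    def add(term_id: str, category: str, atoms: Sequence[int]) -> None:
        l = len(atoms)
        k = sum(1 for a in atoms if int(a) in solute)
        if category in sel.categories and k == l:
            bucket = "UU"
        elif category in sel.categories and 0 < k < l:
            bucket = "UV"
        else:
            bucket = "VV"
        out.append(TermClass(term_id, category, k, l, bucket))

    for t, row in enumerate(system.bonds):
        add(f"bond[{t}]", "bond", row)
    for t, row in enumerate(system.angles):
        add(f"angle[{t}]", "angle", row)
    for t, row in enumerate(system.dihedrals):
        add(f"dihedral[{t}]", "dihedral", row)
    for i, j in system.nonbonded_pairs:
        add(f"vdw[{i}-{j}]", "vdw", (i, j))
        add(f"elec[{i}-{j}]", "elec", (i, j))
    return out


# ---------------------------------------------------------------------------
# raw term energies (batched: x may be (N, 3) or (M, N, 3))


def _bond_energies(x, idx, k, r0):
    if not len(idx):
        return np.zeros(x.shape[:-2] + (0,))
    d = x[..., idx[:, 0], :] - x[..., idx[:, 1], :]
    r = np.linalg.norm(d, axis=-1)
    return 0.5 * k * (r - r0) ** 2


def _angle_values(x, idx):
    u = x[..., idx[:, 0], :] - x[..., idx[:, 1], :]
    v = x[..., idx[:, 2], :] - x[..., idx[:, 1], :]
    cross = np.cross(u, v)
    return np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(u * v, axis=-1))

def _angle_energies(x, idx, k, theta0):
    if not len(idx):
        return np.zeros(x.shape[:-2] + (0,))
    return 0.5 * k * (_angle_values(x, idx) - theta0) ** 2


def dihedral_angles(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Dihedral angles (IUPAC sign convention) for index quadruples.

    x may be (N, 3) or batched (..., N, 3); returns (..., nd) in (-pi, pi].
    """
    x = np.asarray(x, float)
    idx = np.asarray(idx, int).reshape(-1, 4)
    if not len(idx):
        return np.zeros(x.shape[:-2] + (0,))
    b1 = x[..., idx[:, 1], :] - x[..., idx[:, 0], :]
    b2 = x[..., idx[:, 2], :] - x[..., idx[:, 1], :]
    b3 = x[..., idx[:, 3], :] - x[..., idx[:, 2], :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    sin_term = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    cos_term = np.sum(n1 * n2, axis=-1)
    return np.arctan2(sin_term, cos_term)


def _dihedral_energies(x, idx, K, n, delta):
    if not len(idx):
        return np.zeros(x.shape[:-2] + (0,))
    phi = dihedral_angles(x, idx)
    return K * (1.0 + np.cos(n * phi - delta))


def _pair_distances(x, pairs):
    d = x[..., pairs[:, 0], :] - x[..., pairs[:, 1], :]
    return np.linalg.norm(d, axis=-1)


def _lj_energies(r, eps, sig):
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _restraint_energies(x, atoms, k, x0):
    if not len(atoms):
        return np.zeros(x.shape[:-2] + (0,))
    d = x[..., atoms, :] - x0
    return 0.5 * k * np.sum(d * d, axis=-1)


def _corral_energies(x, atoms, k, radius, x0):
    if not len(atoms):
        return np.zeros(x.shape[:-2] + (0,))
    d = x[..., atoms, :] - x0
    excess = np.maximum(np.linalg.norm(d, axis=-1) - radius, 0.0)
    return 0.5 * k * excess**2


# ---------------------------------------------------------------------------
# compiled scaled model


class ScaledToyModel:
    """A (system, selection) pair compiled for batched evaluation.

    Exposes the scaled potential as sum_e lambda**e * C_e(x) + E_vv(x),
    where lambda = beta_m/beta_0 and e runs over the distinct scaling
    exponents k/l present (1 for solute-solute). The exchange criterion,
    the sampler and the force routine all work from this grouped form.
    """

    def __init__(self, system: ToySystem, sel: SoluteSelection):
        sel.validate(system)
        self.system = system
        self.selection = sel
        solute = np.zeros(system.n_atoms, bool)
        solute[list(sel.atom_indices)] = True

        def exps(idx, category):
            if not len(idx):
                return np.zeros(0)
            if category not in sel.categories:
                return np.zeros(len(idx))
            k = solute[idx].sum(axis=1)
            return k / idx.shape[1]

        self._bond_e = np.zeros(len(system.bonds))
        self._angle_e = np.zeros(len(system.angles))
        self._dihedral_e = exps(system.dihedrals, "dihedral")
        self._vdw_e = exps(system.nonbonded_pairs, "vdw")
        self._elec_e = exps(system.nonbonded_pairs, "elec")
        self._pair_eps, self._pair_sig = system.pair_lj_params()
        self._pair_qq = system.pair_charges()
        all_exps = np.concatenate(
            [self._bond_e, self._angle_e, self._dihedral_e, self._vdw_e, self._elec_e]
        )
        nonzero = np.unique(all_exps[all_exps > 0])
        # exponent 0 terms are untempered (VV); keep a stable ascending order
        self.exponents = nonzero
        self._build_kernel_tables()

    def _build_kernel_tables(self) -> None:
        s = self.system
        self._kernel_args = (
            np.ascontiguousarray(s.bonds, np.int64),
            np.ascontiguousarray(s.bond_k), np.ascontiguousarray(s.bond_r0),
            np.ascontiguousarray(self._bond_e),
            np.ascontiguousarray(s.angles, np.int64),
            np.ascontiguousarray(s.angle_k), np.ascontiguousarray(s.angle_theta0),
            np.ascontiguousarray(self._angle_e),
            np.ascontiguousarray(s.dihedrals, np.int64),
            np.ascontiguousarray(s.dihedral_K),
            np.ascontiguousarray(s.dihedral_n, np.float64),
            np.ascontiguousarray(s.dihedral_delta),
            np.ascontiguousarray(self._dihedral_e),
            np.ascontiguousarray(s.nonbonded_pairs, np.int64),
            np.ascontiguousarray(self._pair_eps), np.ascontiguousarray(self._pair_sig),
            np.ascontiguousarray(self._pair_qq),
            np.ascontiguousarray(self._vdw_e), np.ascontiguousarray(self._elec_e),
            np.ascontiguousarray(s.restraint_atoms, np.int64),
            np.ascontiguousarray(s.restraint_k),
            np.ascontiguousarray(s.restraint_x0),
            np.ascontiguousarray(s.corral_atoms, np.int64),
            np.ascontiguousarray(s.corral_k),
            np.ascontiguousarray(s.corral_radius),
            np.ascontiguousarray(s.corral_x0),
        )

        def exp_index(e: float) -> int:
            if e == 0.0:
                return -1
            return int(np.searchsorted(self.exponents, e))

        ei: list[int] = []
        ei.extend(exp_index(e) for e in self._bond_e)
        ei.extend(exp_index(e) for e in self._angle_e)
        ei.extend(exp_index(e) for e in self._dihedral_e)
        for t in range(len(s.nonbonded_pairs)):
            ei.append(exp_index(self._vdw_e[t]))
            ei.append(exp_index(self._elec_e[t]))
        self._term_ei = np.asarray(ei, np.int64)

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms

    @property
    def ndim(self) -> int:
        return 3

    @property
    def masses(self) -> np.ndarray:
        return self.system.masses

    # -- energies ----------------------------------------------------------

    def _term_energy_groups(self, x):
        s = self.system
        r = _pair_distances(x, s.nonbonded_pairs) if len(s.nonbonded_pairs) else None
        return [
            (self._bond_e, _bond_energies(x, s.bonds, s.bond_k, s.bond_r0)),
            (self._angle_e, _angle_energies(x, s.angles, s.angle_k, s.angle_theta0)),
            (self._dihedral_e,
             _dihedral_energies(x, s.dihedrals, s.dihedral_K, s.dihedral_n, s.dihedral_delta)),
            (self._vdw_e,
             _lj_energies(r, self._pair_eps, self._pair_sig) if r is not None
             else np.zeros(x.shape[:-2] + (0,))),
            (self._elec_e,
             self._pair_qq / r if r is not None else np.zeros(x.shape[:-2] + (0,))),
        ]

    #: use the numba kernels for batched evaluation (the numpy routines
    #: remain available as *_numpy and are cross-checked in the tests)
    use_kernels = True

    def energy_components(self, x: np.ndarray):
        """Grouped energies: (components (..., n_exponents), E_vv (...)).

        Scaled total at lambda: sum_e lambda**e components[..., e] + E_vv.
        """
        x = np.asarray(x, float)
        if not np.all(np.isfinite(x)):
            raise ModelError("non-finite coordinates")
        if self.use_kernels:
            from . import _kernels

            batch = x.shape[:-2]
            X = np.ascontiguousarray(x.reshape((-1,) + x.shape[-2:]))
            comps, evv = _kernels.energy_components(
                X, np.empty(0), self.exponents, self._term_ei, self._kernel_args
            )
            return comps.reshape(batch + (len(self.exponents),)), evv.reshape(batch)
        return self.energy_components_numpy(x)

    def energy_components_numpy(self, x: np.ndarray):
        """Reference numpy implementation of :meth:`energy_components`."""
        x = np.asarray(x, float)
        batch = x.shape[:-2]
        comps = np.zeros(batch + (len(self.exponents),))
        evv = np.zeros(batch)
        for exps, energies in self._term_energy_groups(x):
            if not energies.shape[-1]:
                continue
            evv += np.sum(energies[..., exps == 0], axis=-1)
            for ei, e in enumerate(self.exponents):
                m = exps == e
                if m.any():
                    comps[..., ei] += np.sum(energies[..., m], axis=-1)
        s = self.system
        evv += np.sum(
            _restraint_energies(x, s.restraint_atoms, s.restraint_k, s.restraint_x0), axis=-1
        )
        evv += np.sum(
            _corral_energies(x, s.corral_atoms, s.corral_k, s.corral_radius, s.corral_x0),
            axis=-1,
        )
        return comps, evv

    def scaled_energy(self, x: np.ndarray, lam) -> np.ndarray:
        """E_m at lambda = beta_m/beta_0; lam scalar or one per batch row."""
        x = np.asarray(x, float)
        if self.use_kernels and x.ndim in (2, 3):
            from . import _kernels

            single = x.ndim == 2
            X = np.ascontiguousarray(x[None] if single else x)
            lam_arr = np.ascontiguousarray(
                np.broadcast_to(np.asarray(lam, float), X.shape[:1]), float
            )
            out = _kernels.scaled_energies(X, lam_arr, self._kernel_args)
            return float(out[0]) if single else out
        comps, evv = self.energy_components(x)
        lam = np.asarray(lam, float)
        return np.sum(comps * lam[..., None] ** self.exponents, axis=-1) + evv

    def decompose(self, x: np.ndarray) -> EnergyDecomposition:
        """Per-term bucket decomposition for a single configuration."""
        x = np.asarray(x, float)
        if x.ndim != 2:
            raise ModelError("decompose expects a single (N, 3) configuration")
        if not np.all(np.isfinite(x)):
            raise ModelError("non-finite coordinates")
        energies = self._term_energies_by_id(x)
        e_uu = 0.0
        e_vv = 0.0
        uv_terms: list[tuple[float, int, int]] = []
        for t in classify_terms(self.system, self.selection):
            e = energies[t.term_id]
            if t.bucket == "UU":
                e_uu += e
            elif t.bucket == "UV":
                uv_terms.append((e, t.k, t.l))
            else:
                e_vv += e
        s = self.system
        e_vv += float(
            np.sum(_restraint_energies(x, s.restraint_atoms, s.restraint_k, s.restraint_x0))
        )
        e_vv += float(
            np.sum(_corral_energies(x, s.corral_atoms, s.corral_k, s.corral_radius,
                                    s.corral_x0))
        )
        return EnergyDecomposition(E_uu=e_uu, uv_terms=uv_terms, E_vv=e_vv)

    def _term_energies_by_id(self, x) -> dict:
        s = self.system
        out: dict[str, float] = {}
        de = _dihedral_energies(x, s.dihedrals, s.dihedral_K, s.dihedral_n, s.dihedral_delta)
        for t in range(len(s.dihedrals)):
            out[f"dihedral[{t}]"] = float(de[t])
        if len(s.nonbonded_pairs):
            r = _pair_distances(x, s.nonbonded_pairs)
            lj = _lj_energies(r, self._pair_eps, self._pair_sig)
            cc = self._pair_qq / r
            for t, (i, j) in enumerate(s.nonbonded_pairs):
                out[f"vdw[{i}-{j}]"] = float(lj[t])
                out[f"elec[{i}-{j}]"] = float(cc[t])
        be = _bond_energies(x, s.bonds, s.bond_k, s.bond_r0)
        for t in range(len(s.bonds)):
            out[f"bond[{t}]"] = float(be[t])
        ae = _angle_energies(x, s.angles, s.angle_k, s.angle_theta0)
        for t in range(len(s.angles)):
            out[f"angle[{t}]"] = float(ae[t])
        return out

    # -- forces ------------------------------------------------------------

    def scaled_forces(self, x: np.ndarray, lam) -> np.ndarray:
        """-grad of the scaled potential; x (N,3) or (M,N,3), lam scalar/(M,)."""
        x = np.asarray(x, float)
        if not np.all(np.isfinite(x)):
            raise ModelError("non-finite coordinates")
        if self.use_kernels:
            from . import _kernels

            single = x.ndim == 2
            X = np.ascontiguousarray(x[None] if single else x)
            lam_arr = np.ascontiguousarray(
                np.broadcast_to(np.asarray(lam, float), X.shape[:1]), float
            )
            F = np.zeros_like(X)
            _kernels.forces_into(X, lam_arr, F, self._kernel_args)
            return F[0] if single else F
        return self.scaled_forces_numpy(x, lam)

    def scaled_forces_numpy(self, x: np.ndarray, lam) -> np.ndarray:
        """Reference numpy implementation of :meth:`scaled_forces`."""
        x = np.asarray(x, float)
        single = x.ndim == 2
        X = x[None] if single else x
        lam_arr = np.broadcast_to(np.asarray(lam, float), X.shape[:1]).astype(float)
        F = np.zeros_like(X)
        s = self.system

        def weights(exps):
            # per-(replica, term) scale factors lambda**e
            return lam_arr[:, None] ** exps[None, :]

        if len(s.bonds):
            self._add_bond_forces(F, X, weights(self._bond_e))
        if len(s.angles):
            self._add_angle_forces(F, X, weights(self._angle_e))
        if len(s.dihedrals):
            self._add_dihedral_forces(F, X, weights(self._dihedral_e))
        if len(s.nonbonded_pairs):
            self._add_pair_forces(F, X, weights(self._vdw_e), weights(self._elec_e))
        if len(s.restraint_atoms):
            d = X[:, s.restraint_atoms, :] - s.restraint_x0
            _scatter_add(F, s.restraint_atoms, -s.restraint_k[None, :, None] * d)
        if len(s.corral_atoms):
            d = X[:, s.corral_atoms, :] - s.corral_x0
            r = np.linalg.norm(d, axis=-1)
            excess = np.maximum(r - s.corral_radius, 0.0)
            coef = -s.corral_k * excess / np.maximum(r, 1e-12)
            _scatter_add(F, s.corral_atoms, coef[..., None] * d)
        return F[0] if single else F

    def _add_bond_forces(self, F, X, w):
        s = self.system
        i, j = s.bonds[:, 0], s.bonds[:, 1]
        d = X[:, i, :] - X[:, j, :]
        r = np.linalg.norm(d, axis=-1)
        coef = -w * s.bond_k * (r - s.bond_r0) / r
        f = coef[..., None] * d
        _scatter_add(F, i, f)
        _scatter_add(F, j, -f)

    def _add_angle_forces(self, F, X, w):
        s = self.system
        ia, ib, ic = s.angles.T
        u = X[:, ia, :] - X[:, ib, :]
        v = X[:, ic, :] - X[:, ib, :]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        uh = u / nu[..., None]
        vh = v / nv[..., None]
        cos_t = np.clip(np.sum(uh * vh, axis=-1), -1.0, 1.0)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        theta = np.arccos(cos_t)
        dU = w * s.angle_k * (theta - s.angle_theta0)
        gA = -(vh - cos_t[..., None] * uh) / (sin_t * nu)[..., None]
        gC = -(uh - cos_t[..., None] * vh) / (sin_t * nv)[..., None]
        fA = -dU[..., None] * gA
        fC = -dU[..., None] * gC
        _scatter_add(F, ia, fA)
        _scatter_add(F, ic, fC)
        _scatter_add(F, ib, -(fA + fC))

    def _add_dihedral_forces(self, F, X, w):
        s = self.system
        i0, i1, i2, i3 = s.dihedrals.T
        b1 = X[:, i1, :] - X[:, i0, :]
        b2 = X[:, i2, :] - X[:, i1, :]
        b3 = X[:, i3, :] - X[:, i2, :]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=-1)
        phi = np.arctan2(
            np.sum(np.cross(n1, n2) * (b2 / nb2[..., None]), axis=-1),
            np.sum(n1 * n2, axis=-1),
        )
        dU = -w * s.dihedral_K * s.dihedral_n * np.sin(s.dihedral_n * phi - s.dihedral_delta)
        n1sq = np.sum(n1 * n1, axis=-1)
        n2sq = np.sum(n2 * n2, axis=-1)
        tA = -(nb2 / n1sq)[..., None] * n1  # dphi/dx0
        tD = (nb2 / n2sq)[..., None] * n2   # dphi/dx3
        sc = (np.sum(b1 * b2, axis=-1) / nb2**2)[..., None]
        tc = (np.sum(b3 * b2, axis=-1) / nb2**2)[..., None]
        gB = -(1.0 + sc) * tA + tc * tD     # dphi/dx1
        gC = sc * tA - (1.0 + tc) * tD      # dphi/dx2
        _scatter_add(F, i0, -dU[..., None] * tA)
        _scatter_add(F, i1, -dU[..., None] * gB)
        _scatter_add(F, i2, -dU[..., None] * gC)
        _scatter_add(F, i3, -dU[..., None] * tD)

    def _add_pair_forces(self, F, X, w_vdw, w_elec):
        s = self.system
        i, j = s.nonbonded_pairs.T
        d = X[:, i, :] - X[:, j, :]
        r2 = np.sum(d * d, axis=-1)
        r = np.sqrt(r2)
        sr6 = (self._pair_sig**2 / r2) ** 3
        # dU/dr * (1/r): LJ + Coulomb, each with its tempering weight
        lj_coef = w_vdw * 4.0 * self._pair_eps * (6.0 * sr6 - 12.0 * sr6 * sr6) / r2
        cc_coef = -w_elec * self._pair_qq / (r2 * r)
        f = -(lj_coef + cc_coef)[..., None] * d
        _scatter_add(F, i, f)
        _scatter_add(F, j, -f)


def _scatter_add(F: np.ndarray, atoms: np.ndarray, contrib: np.ndarray) -> None:
    """F[:, atoms] += contrib with repeated-index accumulation."""
    np.add.at(F, (slice(None), atoms), contrib)


def compile_model(system, sel: SoluteSelection):
    """Bind a system and a solute selection for batched evaluation.

    ToySystem instances compile to :class:`ScaledToyModel`; other system
    kinds (harmonic baths, discrete systems) provide their own `compile`.
    """
    if isinstance(system, ToySystem):
        return ScaledToyModel(system, sel)
    return system.compile(sel)


# ---------------------------------------------------------------------------
# module-level convenience API


def decompose_energy(system, sel: SoluteSelection, x: np.ndarray) -> EnergyDecomposition:
    """Bucket the potential energy of one configuration into E_uu, the
    cross terms (E_uv_i, k_i, l_i), and E_vv under a solute selection."""
    return compile_model(system, sel).decompose(np.asarray(x, float))


def scaled_potential(decomp: EnergyDecomposition, beta_m: float, beta_0: float) -> float:
    """Solute-tempered potential for one replica.

    (beta_m/beta_0) E_uu + sum_i (beta_m/beta_0)**(k_i/l_i) E_uv_i + E_vv.
    """
    if beta_m <= 0 or beta_0 <= 0:
        raise ModelError("inverse temperatures must be positive")
    lam = beta_m / beta_0
    return (
        lam * decomp.E_uu
        + sum(e * lam ** (k / l) for e, k, l in decomp.uv_terms)
        + decomp.E_vv
    )


def scaled_forces(system, sel: SoluteSelection, x: np.ndarray,
                  beta_m: float, beta_0: float) -> np.ndarray:
    """-grad_x of the scaled potential; each term's force carries that
    term's tempering factor (beta_m/beta_0)**(k/l)."""
    if beta_m <= 0 or beta_0 <= 0:
        raise ModelError("inverse temperatures must be positive")
    return compile_model(system, sel).scaled_forces(x, beta_m / beta_0)
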