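"""Term classification, energy decomposition, and the scaled potential."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grestkit.model import (
    EnergyDecomposition,
    ModelError,
    SoluteSelection,
    ToySystem,
    classify_terms,
    compile_model,
    decompose_energy,
    dihedral_angles,
    scaled_forces,
    scaled_potential,
)

from .conftest import random_chain_system, random_selection


def term_by_id(terms, term_id):
    return next(t for t in terms if t.term_id == term_id)


class TestClassifyTerms:
    def test_cross_dihedral_counts_solute_atoms(self):
        """A dihedral with 2 of its 4 atoms in the solute is a cross term."""
        rng = np.random.default_rng(0)
        sys_ = random_chain_system(rng, 8)
        sel = SoluteSelection({4, 5}, "dihedral")
        t = term_by_id(classify_terms(sys_, sel), "dihedral[2]")  # atoms (2,3,4,5)
        assert (t.k, t.l, t.bucket) == (2, 4, "UV")

    def test_pair_outside_solute_is_solvent(self):
        rng = np.random.default_rng(0)
        sys_ = random_chain_system(rng, 10)
        sel = SoluteSelection({4, 5}, "vdw")
        t = term_by_id(classify_terms(sys_, sel), "vdw[0-9]")
        assert (t.k, t.bucket) == (0, "VV")

    def test_pair_fully_inside_is_solute_solute(self):
        rng = np.random.default_rng(0)
        sys_ = random_chain_system(rng, 8)
        sel = SoluteSelection({3, 4}, "elec")
        # atoms 3,4 are bonded, so use a non-excluded inside pair instead
        sel2 = SoluteSelection({3, 6}, "elec")
        t = term_by_id(classify_terms(sys_, sel2), "elec[3-6]")
        assert (t.k, t.l, t.bucket) == (2, 2, "UU")

    def test_unselected_category_goes_to_solvent_bucket(self):
        """Terms of a category not being tempered are solvent-solvent even
        when every atom is in the solute region."""
        rng = np.random.default_rng(1)
        sys_ = random_chain_system(rng, 8)
        sel = SoluteSelection(range(8), "dihedral")
        terms = classify_terms(sys_, sel)
        assert all(t.bucket == "VV" for t in terms if t.category in ("vdw", "elec"))
        assert all(t.bucket == "VV" for t in terms if t.category in ("bond", "angle"))
        assert all(t.bucket == "UU" for t in terms if t.category == "dihedral")

    def test_out_of_range_selection_rejected(self):
        rng = np.random.default_rng(0)
        sys_ = random_chain_system(rng, 6)
        with pytest.raises(ModelError):
            classify_terms(sys_, SoluteSelection({99}, "all"))

    def test_every_term_classified_exactly_once(self):
        rng = np.random.default_rng(2)
        sys_ = random_chain_system(rng, 7)
        terms = classify_terms(sys_, SoluteSelection({1, 2}, "all"))
        n_pairs = len(sys_.nonbonded_pairs)
        expected = len(sys_.bonds) + len(sys_.angles) + len(sys_.dihedrals) + 2 * n_pairs
        assert len(terms) == expected
        assert len({t.term_id for t in terms}) == expected


class TestDecomposeEnergy:
    def test_single_cross_pair(self):
        """Two LJ beads, one in the solute: the pair is the only cross term."""
        sys_ = ToySystem(
            positions=np.array([[0.0, 0, 0], [1.6, 0, 0], [3.2, 0, 0]]),
            masses=np.ones(3), charges=np.zeros(3),
            lj_eps=np.full(3, 0.4), lj_sigma=np.full(3, 1.0),
            bonds=np.array([[0, 1]]), bond_k=[10.0], bond_r0=[1.5],
        )
        dec = decompose_energy(sys_, SoluteSelection({0}, "vdw"), sys_.positions)
        assert dec.E_uu == 0.0
        # cross pair (0, 2): atom 0 in the solute, atom 2 outside
        assert len(dec.uv_terms) == 1
        e, k, l = dec.uv_terms[0]
        assert (k, l) == (1, 2)
        assert e == pytest.approx(4 * 0.4 * ((1 / 3.2) ** 12 - (1 / 3.2) ** 6))
        # E_vv carries the bond plus the solvent-solvent LJ pair (1, 2)
        expected_vv = (0.5 * 10.0 * (1.6 - 1.5) ** 2
                       + 4 * 0.4 * ((1 / 1.6) ** 12 - (1 / 1.6) ** 6))
        assert dec.E_vv == pytest.approx(expected_vv, abs=1e-12)

    def test_empty_solute_puts_everything_in_solvent(self, four_atom_system):
        # an empty solute region: every tempered-category term has k = 0
        dec = decompose_energy(four_atom_system,
                               SoluteSelection([], "all"),
                               four_atom_system.positions)
        assert dec.E_uu == 0.0 and not dec.uv_terms
        assert dec.E_vv == pytest.approx(dec.total)

    def test_bucket_sums_match_per_term_oracle(self, mini_loop):
        """Bucket sums equal an independent per-term re-summation written
        from the raw functional forms."""
        sys_, sel = mini_loop.system, mini_loop.selection
        x = mini_loop.start
        dec = decompose_energy(sys_, sel, x)

        def bond_e(i, j, k, r0):
            return 0.5 * k * (np.linalg.norm(x[i] - x[j]) - r0) ** 2

        def angle_e(i, j, k_, kk, t0):
            u, v = x[i] - x[j], x[k_] - x[j]
            c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            return 0.5 * kk * (np.arccos(np.clip(c, -1, 1)) - t0) ** 2

        solute = sel.atom_indices
        e_uu, e_uv, e_vv = 0.0, 0.0, 0.0

        def put(val, atoms, cat):
            nonlocal e_uu, e_uv, e_vv
            k = sum(a in solute for a in atoms)
            if cat in sel.categories and k == len(atoms):
                e_uu += val
            elif cat in sel.categories and k > 0:
                e_uv += val
            else:
                e_vv += val

        for t, (i, j) in enumerate(sys_.bonds):
            put(bond_e(i, j, sys_.bond_k[t], sys_.bond_r0[t]), (i, j), "bond")
        for t, (i, j, k_) in enumerate(sys_.angles):
            put(angle_e(i, j, k_, sys_.angle_k[t], sys_.angle_theta0[t]),
                (i, j, k_), "angle")
        for t, quad in enumerate(sys_.dihedrals):
            phi = float(dihedral_angles(x, quad[None])[0])
            val = sys_.dihedral_K[t] * (
                1 + np.cos(sys_.dihedral_n[t] * phi - sys_.dihedral_delta[t])
            )
            put(val, tuple(quad), "dihedral")
        for i, j in sys_.nonbonded_pairs:
            r = np.linalg.norm(x[i] - x[j])
            eps = np.sqrt(sys_.lj_eps[i] * sys_.lj_eps[j])
            sig = 0.5 * (sys_.lj_sigma[i] + sys_.lj_sigma[j])
            put(4 * eps * ((sig / r) ** 12 - (sig / r) ** 6), (i, j), "vdw")
            put(sys_.charges[i] * sys_.charges[j] / r, (i, j), "elec")
        for t, i in enumerate(sys_.restraint_atoms):
            e_vv += 0.5 * sys_.restraint_k[t] * np.sum((x[i] - sys_.restraint_x0[t]) ** 2)
        for t, i in enumerate(sys_.corral_atoms):
            ex = max(np.linalg.norm(x[i] - sys_.corral_x0[t]) - sys_.corral_radius[t], 0)
            e_vv += 0.5 * sys_.corral_k[t] * ex**2

        assert dec.E_uu == pytest.approx(e_uu, rel=1e-10)
        assert sum(e for e, _, _ in dec.uv_terms) == pytest.approx(e_uv, rel=1e-10)
        assert dec.E_vv == pytest.approx(e_vv, rel=1e-10)

    def test_non_finite_coordinates_rejected(self, four_atom_system):
        x = four_atom_system.positions.copy()
        x[0, 0] = np.nan
        with pytest.raises(ModelError):
            decompose_energy(four_atom_system, SoluteSelection({0}, "all"), x)


class TestScaledPotential:
    def test_identity_scaling_recovers_total(self, four_atom_system):
        sel = SoluteSelection({0, 1}, "all")
        dec = decompose_energy(four_atom_system, sel, four_atom_system.positions)
        assert scaled_potential(dec, 1.0, 1.0) == pytest.approx(dec.total)

    def test_hand_evaluated_value(self):
        dec = EnergyDecomposition(E_uu=2.0, uv_terms=[(1.0, 1, 2)], E_vv=5.0)
        assert scaled_potential(dec, 0.25, 1.0) == pytest.approx(6.0)

    def test_unity_exponents_collapse_to_rest2_form(self):
        dec = EnergyDecomposition(E_uu=1.5, uv_terms=[(0.7, 2, 2), (0.2, 4, 4)],
                                  E_vv=3.0)
        lam = 0.4
        expected = lam * (1.5 + 0.7 + 0.2) + 3.0
        assert scaled_potential(dec, lam, 1.0) == pytest.approx(expected)

    def test_nonpositive_beta_rejected(self):
        dec = EnergyDecomposition(E_uu=1.0, uv_terms=[], E_vv=0.0)
        with pytest.raises(ModelError):
            scaled_potential(dec, -1.0, 1.0)

    @given(lam1=st.floats(0.05, 1.0), lam2=st.floats(0.05, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_beta_for_positive_buckets(self, lam1, lam2):
        """With E_uu > 0 and all cross energies >= 0, the scaled potential
        is non-decreasing in beta_m."""
        dec = EnergyDecomposition(E_uu=2.0, uv_terms=[(0.5, 1, 2), (1.0, 3, 4)],
                                  E_vv=-1.0)
        lo, hi = sorted((lam1, lam2))
        assert scaled_potential(dec, lo, 1.0) <= scaled_potential(dec, hi, 1.0) + 1e-12


class TestScaledForces:
    @pytest.mark.parametrize("lam", [1.0, 0.37])
    def test_matches_finite_differences(self, mini_loop, lam):
        sys_, sel = mini_loop.system, mini_loop.selection
        rng = np.random.default_rng(4)
        x = mini_loop.start + 0.03 * rng.standard_normal(mini_loop.start.shape)
        model = compile_model(sys_, sel)
        F = scaled_forces(sys_, sel, x, lam, 1.0)
        h = 1e-6
        num = np.zeros_like(x)
        for i in range(x.shape[0]):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                num[i, d] = -(model.scaled_energy(xp, lam)
                              - model.scaled_energy(xm, lam)) / (2 * h)
        assert np.abs(F - num).max() < 1e-6 * max(1.0, np.abs(F).max())

    def test_identity_scaling_equals_unscaled_field(self, four_atom_system):
        selections = [SoluteSelection({0}, "vdw"), SoluteSelection({1, 2}, "all")]
        x = four_atom_system.positions
        ref = scaled_forces(four_atom_system, selections[0], x, 1.0, 1.0)
        for sel in selections[1:]:
            np.testing.assert_allclose(
                scaled_forces(four_atom_system, sel, x, 1.0, 1.0), ref, atol=1e-12
            )

    def test_isolated_atom_feels_nothing(self):
        sys_ = ToySystem(
            positions=np.array([[0.0, 0, 0], [5.0, 0, 0]]),
            masses=np.ones(2), charges=np.zeros(2),
            lj_eps=np.zeros(2), lj_sigma=np.ones(2),
        )
        F = scaled_forces(sys_, SoluteSelection({0}, "all"), sys_.positions, 0.5, 1.0)
        np.testing.assert_allclose(F, 0.0, atol=1e-15)

    def test_kernel_and_numpy_paths_agree(self, mini_loop):
        model = compile_model(mini_loop.system, mini_loop.selection)
        rng = np.random.default_rng(7)
        X = mini_loop.start[None] + 0.1 * rng.standard_normal((4,) + mini_loop.start.shape)
        lam = np.array([1.0, 0.6, 0.3, 0.1])
        F_k = model.scaled_forces(X, lam)
        F_n = model.scaled_forces_numpy(X, lam)
        np.testing.assert_allclose(F_k, F_n, atol=1e-11)
        ck, ek = model.energy_components(X)
        cn, en = model.energy_components_numpy(X)
        np.testing.assert_allclose(ck, cn, atol=1e-11)
        np.testing.assert_allclose(ek, en, atol=1e-11)


class TestInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_bucket_sum_conservation(self, seed):
        """E_uu + sum E_uv,i + E_vv equals the unscaled total for random
        systems and selections."""
        rng = np.random.default_rng(seed)
        sys_ = random_chain_system(rng, int(rng.integers(5, 9)))
        sel = random_selection(rng, sys_.n_atoms)
        x = sys_.positions + 0.05 * rng.standard_normal(sys_.positions.shape)
        dec = decompose_energy(sys_, sel, x)
        model = compile_model(sys_, sel)
        assert dec.total == pytest.approx(float(model.scaled_energy(x, 1.0)), rel=1e-9)

    def test_full_selection_leaves_only_bond_angle_solvent(self, mini_loop):
        """Selecting every atom and every category leaves E_vv holding just
        the never-tempered terms (bonds, angles, restraints, corral)."""
        sys_ = mini_loop.system
        sel = SoluteSelection(range(sys_.n_atoms), "all")
        x = mini_loop.start
        dec = decompose_energy(sys_, sel, x)
        from grestkit.model import (
            _angle_energies,
            _bond_energies,
            _corral_energies,
            _restraint_energies,
        )

        expected = (
            float(np.sum(_bond_energies(x, sys_.bonds, sys_.bond_k, sys_.bond_r0)))
            + float(np.sum(_angle_energies(x, sys_.angles, sys_.angle_k,
                                           sys_.angle_theta0)))
            + float(np.sum(_restraint_energies(x, sys_.restraint_atoms,
                                               sys_.restraint_k, sys_.restraint_x0)))
            + float(np.sum(_corral_energies(x, sys_.corral_atoms, sys_.corral_k,
                                            sys_.corral_radius, sys_.corral_x0)))
        )
        assert not dec.uv_terms  # whole system inside: no cross terms
        assert dec.E_vv == pytest.approx(expected, rel=1e-10)

    def test_exclusions_require_12_13_pairs(self):
        with pytest.raises(ModelError):
            ToySystem(
                positions=np.zeros((3, 3)) + np.arange(3)[:, None],
                masses=np.ones(3), charges=np.zeros(3),
                lj_eps=np.ones(3), lj_sigma=np.ones(3),
                bonds=np.array([[0, 1], [1, 2]]), bond_k=[1, 1], bond_r0=[1, 1],
                exclusions={(0, 1)},  # missing (1,2) and the 1-3 pair (0,2)
            )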