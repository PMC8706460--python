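# grestkit

Desk-scale replica exchange with solute tempering (gREST, with its REST2
and temperature-replica-exchange special cases) on toy molecular
systems, for studying *which* scaled energy terms best sample a flexible
loop region.

## The problem and the method

Enhanced sampling of a flexible loop on a rigid scaffold — the
antibody/nanobody CDR-H3 loop is the motivating case — fails with plain
MD when the start structure sits in the wrong conformational basin
(e.g. a cis peptide bond from a homology model). Solute tempering runs
M replicas at one bath temperature T_0 = 1/(k_B β_0) and scales the
energy terms of a chosen "solute" region differently per replica:

    E_m(x) = (β_m/β_0) E_uu + Σ_i (β_m/β_0)^(k_i/l_i) E_uv,i + E_vv

where E_uu, E_uv,i, E_vv are the solute–solute, i-th solute–solvent
cross, and solvent–solvent buckets of the potential, and k_i/l_i is the
fraction of the i-th cross term's atoms inside the solute. Neighbor
replicas exchange their scaling parameters β_m with Metropolis
probability min(1, e^(−Δ)),

    Δ = (β_n − β_m)(E_uu(x_a) − E_uu(x_b))
      + Σ_i β_0^(1−k_i/l_i)(β_n^(k_i/l_i) − β_m^(k_i/l_i))(E_uv,i(x_a) − E_uv,i(x_b)),

in which E_vv cancels exactly — so, unlike temperature replica
exchange, acceptance does not collapse with system size. The solute can
be any atom region combined with any subset of the tempered categories
{dihedral, vdW, electrostatic}; bond and angle terms are never
tempered.

The package provides, in reduced units (k_B = 1) on synthetic systems:

* `grestkit.model` — bead-chain force field (bonds, angles,
  cosine-series dihedrals, LJ 12-6, Coulomb, restraints), term
  classification against a solute selection, the scaled potential and
  its forces (numba-compiled, with a numpy reference path);
* `grestkit.sampling` — BAOAB Langevin and Metropolis MC propagation,
  the exchange criterion, the gREST driver, and a ladder optimizer that
  tunes rung spacing to a target neighbor acceptance (default 0.3);
* `grestkit.analysis` — trajectory demultiplexing into
  constant-parameter streams, Kabsch RMSD, distance-matrix PCA,
  exchange statistics and round trips, and the energy–RMSD diagnostic;
* `grestkit.fixtures` — harmonic baths with quadrature oracles, the
  bistable "mini-loop" (a cis/trans dihedral on a loop bridging a
  restrained framework arc), and exactly enumerable discrete systems;
* `grest` — a CLI (`generate`, `run`, `optimize-ladder`, `analyze`)
  over TOML configs, Cα-dialect PDB, HDF5 trajectories and TSV logs.

## Worked example

Temper only the dihedral terms of the mini-loop's loop beads and
compare the physical (β_1) stream with the reference structure:

```python
import numpy as np
from grestkit.fixtures import make_mini_loop, count_well_transitions
from grestkit.sampling import ParameterLadder, run_grest
from grestkit.analysis import (sort_by_parameter, exchange_statistics,
                               rmsd, distance_matrix_pca)

ml = make_mini_loop()                       # start = cis, reference = trans
sel = ml.selection_with("dihedral")         # temper dihedral terms only
ladder = ParameterLadder.geometric(6, 1.0, 10.0)
traj, log = run_grest(ml.system, sel, ladder, 60_000,
                      exchange_interval=100, save_interval=100,
                      seed=31, x0=ml.start)

st = sort_by_parameter(traj)                # per-rung streams; st.beta1 is physical
stats = exchange_statistics(log)
phis = ml.bistable_angles(st.beta1[0])
series = rmsd(st.beta1[0], ml.reference, ml.framework_atoms, ml.loop_atoms)
scores, eig = distance_matrix_pca(st.beta1[0], ml.loop_atoms, 2)

print(f"mean acceptance {stats.mean_acceptance:.3f}")
print("round trips", stats.round_trips.tolist())
print("cis/trans transitions at beta1:", count_well_transitions(phis))
print(f"loop RMSD: first {series[0]:.2f}  min {series.min():.2f}")
print(f"PCA eigenvalues: {eig[0]:.2f} {eig[1]:.2f}")
```

Output:

    mean acceptance 0.603
    round trips [6, 2, 0, 3, 2, 0]
    cis/trans transitions at beta1: 11
    loop RMSD: first 1.38  min 0.76
    PCA eigenvalues: 10.20 3.56

The unscaled single-replica run from the same start crosses the barrier
zero times at this length; with the loop dihedrals tempered, the β_1
stream flips cis↔trans 11 times, its loop RMSD to the reference drops
from 1.38 to 0.76, and PC1 of the loop's distance-matrix PCA separates
the two dihedral states (cluster means +4.0 for cis vs −1.7 for trans).
Geometric ladders over-accept; `optimize_ladder` tunes the spacing to
≈ 0.3 per pair.

The same pipeline runs from the shell:

    grest generate --kind mini_loop --out fix --seed 3
    grest optimize-ladder --config run.toml --out opt --seed 3
    grest run --config run.toml --out out --seed 5
    grest analyze rmsd --traj out/trajectory.h5 --reference fix/reference.pdb --out rmsd.tsv

See `docs/methods.md` for the model, the ladder-update rule, fixture
design rationale, and limitations.

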