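"""File formats: TOML system/run configs, Cα-dialect PDB, HDF5
trajectories, delimited-text exchange logs, and run manifests.

System definition file (TOML). Sections:

    [system]            # per-atom arrays, all the same length
    positions = [[x, y, z], ...]
    masses = [...]      charges = [...]
    lj_eps = [...]      lj_sigma = [...]

    [bonds]   indices = [[i, j], ...];      k = [...]; r0 = [...]
    [angles]  indices = [[i, j, k], ...];   k = [...]; theta0 = [...]
    [dihedrals] indices = [[i,j,k,l], ...]; K = [...]; n = [...]; delta = [...]
    [restraints] atoms = [...]; k = [...]; x0 = [[x,y,z], ...]
    [corral]    atoms = [...]; k = [...]; radius = [...]; x0 = [[x,y,z], ...]
    [selection] atoms = [...]; categories = ["dihedral", "vdw", "elec"] | "all"

All quantities are in reduced units (k_B = 1). Omitted sections default
to empty; exclusions are derived from the bond graph (1-2 and 1-3).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from .model import SoluteSelection, ToySystem
from .sampling import ExchangeLog, Trajectory

__all__ = [
    "load_system",
    "save_system",
    "read_ca_pdb",
    "write_ca_pdb",
    "save_trajectory",
    "load_trajectory",
    "save_exchange_log",
    "load_exchange_log",
    "write_manifest",
    "file_sha256",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TOML system files


def load_system(path) -> tuple[ToySystem, SoluteSelection | None]:
    """Read a system-definition TOML file; returns the system and the
    solute selection if a [selection] section is present."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        sysdoc = doc["system"]
        system = ToySystem(
            positions=np.asarray(sysdoc["positions"], float),
            masses=np.asarray(sysdoc["masses"], float),
            charges=np.asarray(sysdoc["charges"], float),
            lj_eps=np.asarray(sysdoc["lj_eps"], float),
            lj_sigma=np.asarray(sysdoc["lj_sigma"], float),
            bonds=np.asarray(doc.get("bonds", {}).get("indices", []), int).reshape(-1, 2),
            bond_k=doc.get("bonds", {}).get("k", []),
            bond_r0=doc.get("bonds", {}).get("r0", []),
            angles=np.asarray(doc.get("angles", {}).get("indices", []), int).reshape(-1, 3),
            angle_k=doc.get("angles", {}).get("k", []),
            angle_theta0=doc.get("angles", {}).get("theta0", []),
            dihedrals=np.asarray(
                doc.get("dihedrals", {}).get("indices", []), int
            ).reshape(-1, 4),
            dihedral_K=doc.get("dihedrals", {}).get("K", []),
            dihedral_n=doc.get("dihedrals", {}).get("n", []),
            dihedral_delta=doc.get("dihedrals", {}).get("delta", []),
            restraint_atoms=doc.get("restraints", {}).get("atoms", []),
            restraint_k=doc.get("restraints", {}).get("k", []),
            restraint_x0=np.asarray(
                doc.get("restraints", {}).get("x0", []), float
            ).reshape(-1, 3),
            corral_atoms=doc.get("corral", {}).get("atoms", []),
            corral_k=doc.get("corral", {}).get("k", []),
            corral_radius=doc.get("corral", {}).get("radius", []),
            corral_x0=np.asarray(doc.get("corral", {}).get("x0", []), float).reshape(-1, 3),
        )
    except KeyError as e:
        raise ConfigError(f"system file {path} is missing required key {e}") from e
    sel = None
    if "selection" in doc:
        sel = SoluteSelection(
            doc["selection"]["atoms"], doc["selection"].get("categories", "all")
        )
        sel.validate(system)
    return system, sel


def _toml_array(values, fmt="{:.12g}") -> str:
    arr = np.asarray(values)
    if arr.ndim == 1:
        if arr.dtype.kind in "iu":
            return "[" + ", ".join(str(int(v)) for v in arr) + "]"
        return "[" + ", ".join(fmt.format(float(v)) for v in arr) + "]"
    rows = ", ".join(_toml_array(row, fmt) for row in arr)
    return f"[{rows}]"


def save_system(path, system: ToySystem, sel: SoluteSelection | None = None) -> None:
    """Write a system (and optionally its solute selection) as TOML."""
    lines = ["[system]"]
    lines.append(f"positions = {_toml_array(system.positions)}")
    for name in ("masses", "charges", "lj_eps", "lj_sigma"):
        lines.append(f"{name} = {_toml_array(getattr(system, name))}")
    if len(system.bonds):
        lines += ["", "[bonds]",
                  f"indices = {_toml_array(system.bonds)}",
                  f"k = {_toml_array(system.bond_k)}",
                  f"r0 = {_toml_array(system.bond_r0)}"]
    if len(system.angles):
        lines += ["", "[angles]",
                  f"indices = {_toml_array(system.angles)}",
                  f"k = {_toml_array(system.angle_k)}",
                  f"theta0 = {_toml_array(system.angle_theta0)}"]
    if len(system.dihedrals):
        lines += ["", "[dihedrals]",
                  f"indices = {_toml_array(system.dihedrals)}",
                  f"K = {_toml_array(system.dihedral_K)}",
                  f"n = {_toml_array(system.dihedral_n)}",
                  f"delta = {_toml_array(system.dihedral_delta)}"]
    if len(system.restraint_atoms):
        lines += ["", "[restraints]",
                  f"atoms = {_toml_array(system.restraint_atoms)}",
                  f"k = {_toml_array(system.restraint_k)}",
                  f"x0 = {_toml_array(system.restraint_x0)}"]
    if len(system.corral_atoms):
        lines += ["", "[corral]",
                  f"atoms = {_toml_array(system.corral_atoms)}",
                  f"k = {_toml_array(system.corral_k)}",
                  f"radius = {_toml_array(system.corral_radius)}",
                  f"x0 = {_toml_array(system.corral_x0)}"]
    if sel is not None:
        cats = ", ".join(f'"{c}"' for c in sorted(sel.categories))
        lines += ["", "[selection]",
                  f"atoms = {_toml_array(np.asarray(sorted(sel.atom_indices), int))}",
                  f"categories = [{cats}]"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cα-dialect PDB (one bead = one CA record)


def write_ca_pdb(path, coords: np.ndarray, bfactors=None) -> None:
    """Write bead coordinates as consecutive Cα ATOM records (chain A,
    residue ALA, one bead per residue). Reduced length units are written
    verbatim into the Å columns."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, float)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.res_name = np.full(n, "ALA")
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.full(n, "A")
    atoms.hetero = np.zeros(n, bool)
    if bfactors is not None:
        atoms.set_annotation("b_factor", np.asarray(bfactors, float))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_ca_pdb(path) -> np.ndarray:
    """Cα coordinates from a standard PDB file, in file order."""
    from biotite.structure.io.pdb import PDBFile

    try:
        atoms = PDBFile.read(str(path)).get_structure(model=1)
    except Exception as e:
        raise ConfigError(f"cannot parse PDB {path}: {e}") from e
    ca = atoms[atoms.atom_name == "CA"]
    if len(ca) == 0:
        raise ConfigError(f"no CA records in {path}")
    return np.asarray(ca.coord, float)


# ---------------------------------------------------------------------------
# trajectories and logs


def save_trajectory(path, traj: Trajectory, seed: int | None = None) -> None:
    """HDF5 layout: datasets steps, coords, param_index, components, evv,
    scaled_energy; attrs betas, beta_0, exponents, seed."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("steps", "coords", "param_index", "components", "evv",
                     "scaled_energy"):
            fh.create_dataset(name, data=getattr(traj, name))
        fh.attrs["betas"] = traj.betas
        fh.attrs["beta_0"] = traj.beta_0
        fh.attrs["exponents"] = traj.exponents
        if seed is not None:
            fh.attrs["seed"] = seed


def load_trajectory(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        return Trajectory(
            steps=fh["steps"][:], coords=fh["coords"][:],
            param_index=fh["param_index"][:], components=fh["components"][:],
            evv=fh["evv"][:], scaled_energy=fh["scaled_energy"][:],
            exponents=np.asarray(fh.attrs["exponents"]),
            betas=np.asarray(fh.attrs["betas"]), beta_0=float(fh.attrs["beta_0"]),
        )


def save_exchange_log(path, log: ExchangeLog, snapshot_path=None) -> None:
    """Attempts as TSV (step, pair, delta, accepted); mapping snapshots,
    if requested, as a second TSV (step, rung of replica 0, 1, ...)."""
    import pandas as pd

    pd.DataFrame({
        "step": log.steps, "pair": log.pairs,
        "delta": log.deltas, "accepted": np.asarray(log.accepted, int),
    }).to_csv(path, sep="\t", index=False)
    if snapshot_path is not None and log.snapshots:
        snaps = np.asarray(log.snapshots)
        df = pd.DataFrame(snaps, columns=[f"replica_{a}" for a in range(snaps.shape[1])])
        df.insert(0, "step", log.snapshot_steps)
        df.to_csv(snapshot_path, sep="\t", index=False)


def load_exchange_log(path, n_params: int, snapshot_path=None) -> ExchangeLog:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    log = ExchangeLog(
        n_params=n_params,
        steps=df["step"].tolist(), pairs=df["pair"].tolist(),
        deltas=df["delta"].tolist(), accepted=df["accepted"].astype(bool).tolist(),
    )
    if snapshot_path is not None and Path(snapshot_path).exists():
        sdf = pd.read_csv(snapshot_path, sep="\t")
        log.snapshot_steps = sdf["step"].tolist()
        cols = [c for c in sdf.columns if c.startswith("replica_")]
        log.snapshots = [row.to_numpy() for _, row in sdf[cols].iterrows()]
    return log


# ---------------------------------------------------------------------------
# manifests


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, seed: int, config: dict, outputs) -> None:
    """Provenance record: resolved config, seed, code version, and a
    sha256 inventory of the produced files."""
    from . import __version__

    inventory = {
        str(Path(p).name): file_sha256(p) for p in outputs if Path(p).exists()
    }
    doc = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": inventory,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")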