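"""Solvent-replica generation: overlay, tile, cull, and write PDB.

The classic solvation recipe — overlay the solute with an equilibrated
periodic solvent-box snapshot and delete clashing waters — is arbitrary in
exactly the ways that make it useful for generating independent replicas:
any snapshot, rotation or translation of the solvent box is equally valid
and produces a different water arrangement (and count).  :func:`solvate`
makes that arbitrariness explicit and seeded, and
:func:`ensemble_manifest` records a velocity-seeded (VIS) or
solvent-seeded (SIS) replica plan.

Geometry only: no energies, no minimisation, no topology files.  PDB
reading and writing goes through biotite (HETATM waters, CRYST1 box).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomSet",
    "WaterBox",
    "SolvatedSystem",
    "solvate",
    "ensemble_manifest",
    "read_pdb",
    "write_pdb",
    "write_water_box_pdb",
    "read_water_box_pdb",
]


@dataclasses.dataclass(frozen=True)
class AtomSet:
    """Minimal solute representation: names, residues, elements, coordinates (Å)."""

    names: np.ndarray
    residues: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None  # cubic box vectors (3,) or None

    def __post_init__(self):
        xyz = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "names", np.asarray(self.names, dtype=object))
        object.__setattr__(self, "residues", np.asarray(self.residues, dtype=object))
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=object))
        if xyz.size and not np.all(np.isfinite(xyz)):
            raise ValueError("solute coordinates must be finite")
        if not (len(self.names) == len(self.residues) == len(self.elements) == len(xyz)):
            raise ValueError("per-atom annotation arrays must have equal length")

    @classmethod
    def empty(cls) -> "AtomSet":
        return cls(names=np.array([], dtype=object),
                   residues=np.array([], dtype=object),
                   elements=np.array([], dtype=object),
                   coords=np.zeros((0, 3)))

    @classmethod
    def single_atom(cls, position, name: str = "C1", element: str = "C") -> "AtomSet":
        return cls(names=np.array([name], dtype=object),
                   residues=np.array(["LIG"], dtype=object),
                   elements=np.array([element], dtype=object),
                   coords=np.asarray(position, dtype=float).reshape(1, 3))

    def __len__(self) -> int:
        return len(self.coords)


@dataclasses.dataclass(frozen=True)
class WaterBox:
    """Cubic snapshot of rigid three-site waters.

    ``waters`` has shape (n_waters, 3, 3): per water the O, H, H positions
    in Å.  All oxygens must lie inside the box; O–H bond lengths must match
    the rigid model (0.9572 Å) to within 1%.
    """

    snapshot_id: int
    edge: float
    waters: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray(self.waters, dtype=float)
        object.__setattr__(self, "waters", w)
        if w.ndim != 3 or w.shape[1:] != (3, 3):
            raise ValueError("waters must have shape (n, 3 sites, 3 coords)")
        if self.edge <= 0:
            raise ValueError("box edge must be positive")
        oxy = w[:, 0, :]
        if w.shape[0] and (oxy.min() < -1e-6 or oxy.max() > self.edge + 1e-6):
            raise ValueError("all oxygen positions must lie inside the box")
        if w.shape[0]:
            oh = np.linalg.norm(w[:, 1:, :] - w[:, :1, :], axis=-1)
            if np.any(np.abs(oh - 0.9572) > 0.01 * 0.9572):
                raise ValueError("O-H bond lengths deviate >1% from the rigid model")

    @property
    def n_waters(self) -> int:
        return self.waters.shape[0]


@dataclasses.dataclass(frozen=True)
class SolvatedSystem:
    """Solute plus retained overlay waters in the final cubic box."""

    solute: AtomSet
    waters: np.ndarray  # (n, 3, 3) in the final box frame
    box_edge: float
    provenance: dict

    @property
    def n_waters(self) -> int:
        return self.waters.shape[0]

    def min_solute_water_distance(self) -> float:
        if len(self.solute) == 0 or self.n_waters == 0:
            return np.inf
        d = np.linalg.norm(
            self.waters.reshape(-1, 1, 3) - self.solute.coords[None, :, :], axis=-1
        )
        return float(d.min())


def _random_rigid_transform(rng: np.random.Generator, period: float):
    """Uniform rotation (quaternion method) + translation within one period."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(0.0, period, size=3)
    return rot, trans


def solvate(
    solute: AtomSet,
    box: WaterBox,
    margin: float = 12.0,
    cutoff: float = 2.4,
    seed: int | None = 0,
) -> SolvatedSystem:
    """Overlay a solute with a (transformed, tiled) water-box snapshot.

    The target box is the solute bounding box extended by ``margin`` on
    every side and cubified; the solute is centred in it.  The snapshot is
    rigidly rotated and translated by a seeded random transform
    (``seed=None`` keeps the identity transform), tiled periodically to
    cover the target box, and every water with ANY atom within ``cutoff``
    of ANY solute atom is deleted whole.  Deterministic under fixed
    (snapshot, seed).
    """
    if margin <= 0 or cutoff <= 0:
        raise ValueError("margin and cutoff must be positive")
    if box.n_waters == 0:
        raise ValueError("water box contains no waters")
    if cutoff >= margin:
        warnings.warn(
            "clash cutoff >= solvation margin: culling will be pathological",
            stacklevel=2,
        )

    if len(solute):
        lo, hi = solute.coords.min(axis=0), solute.coords.max(axis=0)
        edge = float((hi - lo).max() + 2.0 * margin)
        center = 0.5 * (lo + hi)
    else:
        edge = 2.0 * margin
        center = np.zeros(3)
    solute_coords = solute.coords - center + edge / 2.0
    solute_in_box = dataclasses.replace(
        solute, coords=solute_coords, box=np.full(3, edge)
    )

    if seed is None:
        rot, trans = np.eye(3), np.zeros(3)
    else:
        rot, trans = _random_rigid_transform(np.random.default_rng(seed), box.edge)
    moved = box.waters @ rot.T + trans

    # Tile images of the (rotated) periodic snapshot until the target box is
    # covered; a water belongs to the system if its oxygen lands inside.
    period = box.edge
    lattice = rot * period  # columns scaled: image shift for n is rot @ (period*n)
    n_max = int(np.ceil(edge / period)) + 1
    shifts = np.arange(-n_max, n_max + 1)
    kept = []
    for nx in shifts:
        for ny in shifts:
            for nz in shifts:
                shift = lattice @ np.array([nx, ny, nz], dtype=float)
                img = moved + shift
                oxy = img[:, 0, :]
                inside = np.all((oxy >= 0.0) & (oxy < edge), axis=1)
                if inside.any():
                    kept.append(img[inside])
    waters = np.concatenate(kept, axis=0) if kept else np.zeros((0, 3, 3))

    if len(solute_in_box) and waters.shape[0]:
        tree = cKDTree(solute_in_box.coords)
        dmin = tree.query(waters.reshape(-1, 3))[0].reshape(waters.shape[0], 3)
        clash = (dmin < cutoff).any(axis=1)
        waters = waters[~clash]
        removed = int(clash.sum())
    else:
        removed = 0

    return SolvatedSystem(
        solute=solute_in_box,
        waters=waters,
        box_edge=edge,
        provenance={
            "snapshot_id": box.snapshot_id,
            "seed": seed,
            "rotation": rot.tolist(),
            "translation": trans.tolist(),
            "cutoff": cutoff,
            "margin": margin,
            "waters_removed": removed,
        },
    )


def ensemble_manifest(
    mode: str,
    replicates: int,
    snapshot_ids: list[int] | None = None,
    velocity_seeds: list[int] | None = None,
    structure: str = "system.pdb",
    net_charge: int = 0,
) -> dict:
    """Replica plan for a VIS or SIS ensemble.

    VIS: one starting structure, ``replicates`` distinct velocity seeds.
    SIS: one structure per solvent snapshot, each with its own fresh
    velocity seed (solvent-replica runs randomise velocities too).
    Counterions are not placed; the required net charge is recorded as
    metadata only.
    """
    mode = mode.upper()
    if mode not in ("VIS", "SIS"):
        raise ValueError("mode must be 'VIS' or 'SIS'")
    if replicates < 1:
        raise ValueError("at least one replicate is required")
    if velocity_seeds is None:
        velocity_seeds = list(range(1, replicates + 1))
    if len(velocity_seeds) != replicates:
        raise ValueError("need one velocity seed per replicate")
    entries = []
    if mode == "VIS":
        for i, vseed in enumerate(velocity_seeds, start=1):
            entries.append(
                {"replicate": i, "structure": structure, "velocity_seed": vseed}
            )
    else:
        if snapshot_ids is None or len(snapshot_ids) != replicates:
            raise ValueError("SIS mode requires one snapshot id per replicate")
        if len(set(snapshot_ids)) != len(snapshot_ids):
            raise ValueError("duplicate snapshot ids in SIS mode")
        for i, (snap, vseed) in enumerate(zip(snapshot_ids, velocity_seeds), start=1):
            entries.append(
                {
                    "replicate": i,
                    "structure": f"system_box{snap}.pdb",
                    "snapshot_id": snap,
                    "velocity_seed": vseed,
                }
            )
    return {
        "mode": mode,
        "replicates": replicates,
        "net_charge": net_charge,
        "entries": entries,
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _water_atom_array(waters: np.ndarray, edge: float) -> struc.AtomArray:
    n = waters.shape[0]
    arr = struc.AtomArray(3 * n)
    arr.coord = waters.reshape(-1, 3).astype(np.float32)
    arr.chain_id[:] = "W"
    arr.res_id = np.repeat(np.arange(1, n + 1), 3)
    arr.res_name[:] = "HOH"
    arr.hetero[:] = True
    arr.atom_name = np.tile(["O", "H1", "H2"], n)
    arr.element = np.tile(["O", "H", "H"], n)
    arr.box = np.eye(3, dtype=np.float32) * edge
    return arr


def write_water_box_pdb(box: WaterBox, path) -> None:
    """Write a water box as HETATM waters with a CRYST1 record."""
    pdb = PDBFile()
    pdb.set_structure(_water_atom_array(box.waters, box.edge))
    pdb.write(str(path))


def read_water_box_pdb(path, snapshot_id: int = 0) -> WaterBox:
    """Read a 3-site water box written by :func:`write_water_box_pdb`."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    if arr.box is None:
        raise ValueError("water-box PDB must carry a CRYST1 record")
    edge = float(arr.box[0, 0])
    coords = np.asarray(arr.coord, dtype=float)
    if coords.shape[0] % 3 != 0:
        raise ValueError("water-box PDB must contain whole 3-site waters")
    return WaterBox(
        snapshot_id=snapshot_id, edge=edge, waters=coords.reshape(-1, 3, 3)
    )


def write_pdb(system: SolvatedSystem, path) -> None:
    """Write a solvated system: solute ATOM records, then HETATM waters."""
    n_s = len(system.solute)
    n_w = system.n_waters
    arr = struc.AtomArray(n_s + 3 * n_w)
    if n_s:
        arr.coord[:n_s] = system.solute.coords.astype(np.float32)
        arr.chain_id[:n_s] = "A"
        arr.res_id[:n_s] = 1
        arr.res_name[:n_s] = system.solute.residues.astype("U5")
        arr.atom_name[:n_s] = system.solute.names.astype("U6")
        arr.element[:n_s] = system.solute.elements.astype("U2")
        arr.hetero[:n_s] = False
    if n_w:
        wat = _water_atom_array(system.waters, system.box_edge)
        arr.coord[n_s:] = wat.coord
        arr.chain_id[n_s:] = "W"
        arr.res_id[n_s:] = wat.res_id + 1
        arr.res_name[n_s:] = "HOH"
        arr.atom_name[n_s:] = wat.atom_name
        arr.element[n_s:] = wat.element
        arr.hetero[n_s:] = True
    arr.box = np.eye(3, dtype=np.float32) * system.box_edge
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb(path) -> AtomSet:
    """Read any PDB into an :class:`AtomSet` (box taken from CRYST1 if present)."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    box = None
    if arr.box is not None:
        box = np.asarray(np.diag(arr.box), dtype=float)
    return AtomSet(
        names=np.asarray(arr.atom_name, dtype=object),
        residues=np.asarray(arr.res_name, dtype=object),
        elements=np.asarray(arr.element, dtype=object),
        coords=np.asarray(arr.coord, dtype=float),
        box=box,
    )
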