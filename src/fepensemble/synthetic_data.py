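"""Analytically tractable synthetic systems for every pipeline stage.

Three generators, all seeded with numpy's PCG64 ``default_rng`` (the seed is
recorded in the output so runs are bit-reproducible):

* :func:`gen_harmonic_alchemy` — a ladder of one-dimensional harmonic
  "λ windows" whose free energies are known in closed form,
  Δf(0→i) = ½ ln(k_i / k_0), giving an exact oracle for MBAR/BAR/EXP.
* :func:`gen_replicate_study` — replicate ΔΔG tables emulating a 5+5
  two-condition replicate design with Gaussian replicate scatter and an
  optional systematic offset on one condition.
* :func:`gen_water_box` — rigid three-site waters on a jittered cubic
  lattice with random orientations: a geometric stand-in for an
  equilibrated solvent-box snapshot (no interaction model, no dynamics).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .estimators import ReducedPotentialSet, FreeEnergySet

__all__ = [
    "HarmonicSchedule",
    "ReplicateStudySpec",
    "LAMBDA_11",
    "LAMBDA_13",
    "gen_harmonic_alchemy",
    "gen_replicate_study",
    "gen_water_box",
]

#: default λ ladders mirroring the two study designs
LAMBDA_11 = np.round(np.linspace(0.0, 1.0, 11), 2)
LAMBDA_13 = np.array(
    [0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0]
)

# TIP3P-like rigid water geometry
_OH_BOND = 0.9572  # Å
_HOH_ANGLE = np.deg2rad(104.52)
_WATER_MASS = 18.01528  # g/mol
_AVOGADRO = 6.02214076e23


@dataclasses.dataclass(frozen=True)
class HarmonicSchedule:
    """Ladder of 1-D harmonic states u_k(x) = ½ k_k (x - c_k)².

    The exact dimensionless free energy of state i relative to state 0 is
    ½ ln(k_i / k_0), independent of the centers c_k.
    """

    stiffness: np.ndarray
    offsets: np.ndarray
    samples_per_state: int
    seed: int = 0

    def __post_init__(self):
        k = np.atleast_1d(np.asarray(self.stiffness, dtype=float))
        c = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "stiffness", k)
        object.__setattr__(self, "offsets", c)
        if np.any(k <= 0):
            raise ValueError("all stiffness values must be positive")
        if k.shape != c.shape:
            raise ValueError("stiffness and offsets must have equal length")
        if self.samples_per_state < 1:
            raise ValueError("samples_per_state must be a positive integer")

    @property
    def exact_delta_f(self) -> np.ndarray:
        """Closed-form f_k - f_0 = ½ ln(k_k / k_0)."""
        return 0.5 * np.log(self.stiffness / self.stiffness[0])


def gen_harmonic_alchemy(
    spec: HarmonicSchedule, temperature: float = 300.0
) -> tuple[ReducedPotentialSet, FreeEnergySet]:
    """Sample a harmonic λ ladder and attach its exact free energies.

    Each state k contributes ``samples_per_state`` draws from the Gaussian
    it implies (sd = k_k^{-1/2} around c_k); every draw's reduced potential
    is evaluated at every state.  The returned :class:`FreeEnergySet` holds
    the closed-form free energies (zero covariance), not an estimate.
    """
    rng = np.random.default_rng(spec.seed)
    k, c = spec.stiffness, spec.offsets
    n = spec.samples_per_state
    n_states = k.size
    x = np.concatenate(
        [rng.normal(c[s], 1.0 / np.sqrt(k[s]), size=n) for s in range(n_states)]
    )
    u_kn = 0.5 * k[:, None] * (x[None, :] - c[:, None]) ** 2
    lambdas = (
        np.linspace(0.0, 1.0, n_states) if n_states > 1 else np.array([0.0])
    )
    data = ReducedPotentialSet(
        u_kn=u_kn, n_k=np.full(n_states, n, dtype=np.int64), lambdas=lambdas
    )
    exact = FreeEnergySet(
        f_k=spec.exact_delta_f,
        covariance=np.zeros((n_states, n_states)),
        temperature=temperature,
    )
    return data, exact


@dataclasses.dataclass(frozen=True)
class ReplicateStudySpec:
    """Stated world of a two-condition replicate study.

    ``true_ddg`` maps transformation id -> true ΔΔG (kJ/mol).  Replicates in
    each condition are independent Gaussian draws around the truth with sd
    ``sigma_rep``; the condition named by ``offset_condition`` is shifted by
    ``condition_offset`` (the Eth→Tol situation).  ``sigma_mbar`` is the
    per-replicate estimator precision written into the table.
    """

    true_ddg: dict[str, float]
    sigma_rep: float = 0.39
    sigma_mbar: float = 0.08
    replicates: int = 5
    conditions: tuple[str, str] = ("VIS", "SIS")
    condition_offset: float = 0.0
    offset_condition: str = "SIS"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rep < 0 or self.sigma_mbar < 0:
            raise ValueError("noise scales must be non-negative")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per condition are required")
        if not self.true_ddg:
            raise ValueError("at least one transformation is required")


def gen_replicate_study(
    spec: ReplicateStudySpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a replicate ΔΔG table plus its ground-truth table.

    Returns
    -------
    records : DataFrame with columns
        transformation, condition, replicate, ddg_kjmol, sigma_kjmol
    truth : DataFrame with columns transformation, true_ddg_kjmol,
        expected per-condition means (truth plus any offset)
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for name, mu in spec.true_ddg.items():
        for cond in spec.conditions:
            center = mu + (
                spec.condition_offset if cond == spec.offset_condition else 0.0
            )
            values = rng.normal(center, spec.sigma_rep, size=spec.replicates)
            for r, v in enumerate(values, start=1):
                rows.append((name, cond, r, v, spec.sigma_mbar))
            truth_rows.append((name, cond, mu, center))
    records = pd.DataFrame(
        rows,
        columns=["transformation", "condition", "replicate", "ddg_kjmol", "sigma_kjmol"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transformation", "condition", "true_ddg_kjmol", "expected_mean_kjmol"],
    )
    records.attrs["seed"] = spec.seed
    truth.attrs["seed"] = spec.seed
    return records, truth


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform rotation matrices via the quaternion method."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )


def _rigid_water_sites() -> np.ndarray:
    """O, H, H coordinates of one rigid water, O at the origin (Å)."""
    h1 = np.array([_OH_BOND, 0.0, 0.0])
    h2 = np.array(
        [_OH_BOND * np.cos(_HOH_ANGLE), _OH_BOND * np.sin(_HOH_ANGLE), 0.0]
    )
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def gen_water_box(
    edge: float,
    count: int,
    jitter: float = 0.2,
    seed: int = 0,
    snapshot_id: int | None = None,
):
    """Rigid three-site waters on a jittered cubic lattice in a cubic box.

    ``count`` oxygens are placed on an n³ lattice (n = ⌈count^⅓⌉) with
    per-axis uniform jitter in [-jitter, jitter] Å and an independent random
    orientation per molecule.  Oxygen positions always stay inside the box.
    An error is raised if the implied lattice spacing would put oxygens
    closer than 2.4 Å (an unphysical density for water).

    Returns a :class:`fepensemble.solvation_setup.WaterBox`.
    """
    from .solvation_setup import WaterBox

    if edge <= 0:
        raise ValueError("box edge must be positive")
    if count < 1:
        raise ValueError("water count must be positive")
    n = int(np.ceil(count ** (1.0 / 3.0) - 1e-9))
    spacing = edge / n
    if spacing < 2.4:
        raise ValueError(
            f"count {count} in a {edge:.1f} A box implies lattice spacing "
            f"{spacing:.2f} A < 2.4 A between oxygens"
        )
    rng = np.random.default_rng(seed)
    grid = (np.arange(n) + 0.5) * spacing
    sites = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), -1).reshape(-1, 3)
    if count < sites.shape[0]:
        keep = rng.choice(sites.shape[0], size=count, replace=False)
        keep.sort()
        sites = sites[keep]
    if jitter > 0:
        sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
        sites = np.clip(sites, 1e-6, edge - 1e-6)
    rots = _random_rotations(rng, count)
    template = _rigid_water_sites()
    waters = sites[:, None, :] + np.einsum("nij,aj->nai", rots, template)
    return WaterBox(
        snapshot_id=seed if snapshot_id is None else snapshot_id,
        edge=float(edge),
        waters=waters,
        seed=seed,
    )
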