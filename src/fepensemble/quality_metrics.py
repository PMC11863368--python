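"""Prediction-quality statistics for relative binding affinities.

Four measures against experiment, each with a parametric-bootstrap
uncertainty:

* MAD and Max — mean and maximum absolute deviation (kJ/mol);
* R² — squared Pearson correlation computed *bidirectionally*: every
  transformation enters the point set in both directions (x, y) and
  (−x, −y), which removes the arbitrariness of the perturbation direction
  and reduces R² to the zero-mean identity (Σxy)² / (Σx² Σy²);
* τ_r — Kendall rank concordance restricted to the transformations that
  were explicitly simulated (not to all ligand pairs derivable from them);
* τ_r90 — τ_r computed only over estimates that are statistically
  significant at the 90% level (|value| ≥ z·SE, z = 1.645 two-sided
  normal) and over pairs whose experimental values are not exactly tied.

Two Kendall denominators are supported and never silently mixed:
``tie_policy="count"`` divides by all pairs considered (a τ_a-style
denominator, ties contributing zero to the numerator) while
``tie_policy="exclude"`` divides only by the untied pairs.  τ_r defaults
to "count", τ_r90 to "exclude"; both expose the flag.

Experimental lower bounds (a "≥ x" affinity) are used at face value and
flagged in the report.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "QualityReport",
    "signed_errors",
    "mad_max",
    "r2_bidirectional",
    "kendall_tau_r",
    "tau_r90",
    "bootstrap_quality",
]

Z_90_TWO_SIDED = 1.6448536269514722  # two-sided normal 90% quantile

PREDICTION_COLUMNS = ["transformation", "calc", "calc_se", "exp", "exp_bound", "exp_sigma"]


@dataclasses.dataclass(frozen=True)
class PredictionSet:
    """Calculated vs experimental ΔΔG per transformation (kJ/mol).

    ``exp_bound`` marks experimental values that are only lower bounds;
    ``exp_sigma`` is an optional experimental uncertainty (NaN when absent).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        for col, default in (("exp_bound", False), ("exp_sigma", np.nan)):
            if col not in df:
                df[col] = default
        missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"prediction table is missing columns {missing}")
        if df["transformation"].duplicated().any():
            raise ValueError("transformation ids must be unique")
        if (df["calc_se"] < 0).any():
            raise ValueError("calculated SEs must be non-negative")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, transformation, calc, calc_se, exp,
                    exp_bound=None, exp_sigma=None) -> "PredictionSet":
        n = len(transformation)
        return cls(pd.DataFrame({
            "transformation": list(transformation),
            "calc": np.asarray(calc, dtype=float),
            "calc_se": np.asarray(calc_se, dtype=float),
            "exp": np.asarray(exp, dtype=float),
            "exp_bound": np.asarray(exp_bound if exp_bound is not None else [False] * n),
            "exp_sigma": np.asarray(
                exp_sigma if exp_sigma is not None else [np.nan] * n, dtype=float),
        }))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def calc(self) -> np.ndarray:
        return self.frame["calc"].to_numpy(dtype=float)

    @property
    def calc_se(self) -> np.ndarray:
        return self.frame["calc_se"].to_numpy(dtype=float)

    @property
    def exp(self) -> np.ndarray:
        return self.frame["exp"].to_numpy(dtype=float)

    @property
    def exp_sigma(self) -> np.ndarray:
        return self.frame["exp_sigma"].to_numpy(dtype=float)

    @property
    def has_bounds(self) -> bool:
        return bool(self.frame["exp_bound"].any())


@dataclasses.dataclass(frozen=True)
class QualityReport:
    """Point estimates of the four quality measures with bootstrap sds."""

    mad: float
    mad_sd: float
    max: float
    max_sd: float
    r2: float
    r2_sd: float
    tau_r: float
    tau_r_sd: float
    tau_r90: float | None
    tau_r90_sd: float | None
    bootstrap_sets: int
    seed: int
    uses_bound_values: bool = False

    def __post_init__(self):
        if self.mad < 0 or self.max < self.mad:
            raise ValueError("require 0 <= MAD <= Max")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def signed_errors(p: PredictionSet) -> pd.Series:
    """Per-transformation error, calculated − experimental (kJ/mol)."""
    if p.frame["exp"].isna().any():
        bad = p.frame.loc[p.frame["exp"].isna(), "transformation"].iloc[0]
        raise ValueError(f"missing experimental value for '{bad}'")
    return pd.Series(p.calc - p.exp, index=p.frame["transformation"], name="error")


def mad_max(errors) -> tuple[float, float]:
    """Mean and maximum absolute deviation of a set of signed errors."""
    e = np.abs(np.asarray(errors, dtype=float).ravel())
    if e.size == 0:
        raise ValueError("mad_max requires at least one error")
    return float(e.mean()), float(e.max())


def r2_bidirectional(p: PredictionSet) -> float:
    """Squared Pearson correlation over the direction-symmetrised point set.

    Augmenting every (calc, exp) point with (−calc, −exp) gives a set with
    exact zero means, so R² reduces to (Σxy)² / (Σx² Σy²) over the original
    points.
    """
    if len(p) < 2:
        raise ValueError("R^2 requires at least two transformations")
    x, y = p.calc, p.exp
    sxx, syy = float(x @ x), float(y @ y)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in calculated or experimental values")
    return float((x @ y) ** 2 / (sxx * syy))


def _kendall(x: np.ndarray, y: np.ndarray,
             tie_policy: Literal["count", "exclude"]) -> float:
    """Kendall concordance over all pairs by explicit enumeration.

    A pair is concordant/discordant by the sign of the product of its x and
    y differences; pairs tied in either coordinate contribute zero to the
    numerator and, under ``tie_policy="exclude"``, leave the denominator.
    """
    n = x.size
    conc = disc = tied = 0
    for i in range(n - 1):
        dx = x[i + 1:] - x[i]
        dy = y[i + 1:] - y[i]
        s = np.sign(dx) * np.sign(dy)
        conc += int(np.count_nonzero(s > 0))
        disc += int(np.count_nonzero(s < 0))
        tied += int(np.count_nonzero(s == 0))
    denom = conc + disc + (tied if tie_policy == "count" else 0)
    if denom == 0:
        raise ValueError("no untied pairs: Kendall tau is undefined")
    return (conc - disc) / denom


def kendall_tau_r(
    p: PredictionSet, tie_policy: Literal["count", "exclude"] = "count"
) -> float:
    """Kendall τ over the studied transformations only."""
    if len(p) < 2:
        raise ValueError("Kendall tau requires at least two transformations")
    return _kendall(p.calc, p.exp, tie_policy)


def tau_r90(
    p: PredictionSet,
    z: float = Z_90_TWO_SIDED,
    tie_policy: Literal["count", "exclude"] = "exclude",
) -> float | None:
    """Kendall τ restricted to 90%-significant estimates.

    A transformation survives when |calc| ≥ z·SE_calc and, where an
    experimental σ is provided, |exp| ≥ z·σ_exp.  Pairs with exactly tied
    experimental values (a zero experimental difference is never
    significant) are excluded under the default tie policy.  Returns None
    (undefined) when fewer than two transformations survive or no pairs
    remain.
    """
    keep = np.abs(p.calc) >= z * p.calc_se
    has_sigma = np.isfinite(p.exp_sigma)
    keep &= ~has_sigma | (np.abs(p.exp) >= z * np.where(has_sigma, p.exp_sigma, 0.0))
    if int(keep.sum()) < 2:
        return None
    try:
        return _kendall(p.calc[keep], p.exp[keep], tie_policy)
    except ValueError:
        return None


def _point_metrics(
    p: PredictionSet,
    tau_tie_policy: Literal["count", "exclude"],
    tau90_tie_policy: Literal["count", "exclude"],
    z: float,
) -> dict[str, float | None]:
    err = signed_errors(p).to_numpy()
    mad, mx = mad_max(err)
    return {
        "mad": mad,
        "max": mx,
        "r2": r2_bidirectional(p),
        "tau_r": kendall_tau_r(p, tau_tie_policy),
        "tau_r90": tau_r90(p, z=z, tie_policy=tau90_tie_policy),
    }


def bootstrap_quality(
    p: PredictionSet,
    sets: int = 1000,
    seed: int = 0,
    tau_tie_policy: Literal["count", "exclude"] = "count",
    tau90_tie_policy: Literal["count", "exclude"] = "exclude",
    z: float = Z_90_TWO_SIDED,
) -> QualityReport:
    """All four quality measures with parametric-bootstrap uncertainties.

    Each bootstrap set perturbs every calculated value by Gaussian noise
    with its SE (and each experimental value by its σ, where provided),
    recomputes the measures, and the sd over sets is reported as the
    uncertainty.  The central values are the unperturbed point estimates.
    """
    if sets < 2:
        raise ValueError("bootstrap requires at least 2 sets")
    point = _point_metrics(p, tau_tie_policy, tau90_tie_policy, z)
    rng = np.random.default_rng(seed)
    exp_sig = np.where(np.isfinite(p.exp_sigma), p.exp_sigma, 0.0)
    samples: dict[str, list[float]] = {k: [] for k in point}
    base = p.frame
    for _ in range(sets):
        calc = p.calc + rng.normal(0.0, 1.0, size=len(p)) * p.calc_se
        exp = p.exp + rng.normal(0.0, 1.0, size=len(p)) * exp_sig
        pert = PredictionSet(base.assign(calc=calc, exp=exp))
        m = _point_metrics(pert, tau_tie_policy, tau90_tie_policy, z)
        for k, v in m.items():
            if v is not None:
                samples[k].append(v)
    sds = {
        k: (float(np.std(v, ddof=1)) if len(v) > 1 else None)
        for k, v in samples.items()
    }
    return QualityReport(
        mad=point["mad"], mad_sd=sds["mad"] or 0.0,
        max=point["max"], max_sd=sds["max"] or 0.0,
        r2=point["r2"], r2_sd=sds["r2"] or 0.0,
        tau_r=point["tau_r"], tau_r_sd=sds["tau_r"] or 0.0,
        tau_r90=point["tau_r90"], tau_r90_sd=sds["tau_r90"],
        bootstrap_sets=sets, seed=seed,
        uses_bound_values=p.has_bounds,
    )
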