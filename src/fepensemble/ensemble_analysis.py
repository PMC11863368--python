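"""Replicate-ensemble aggregation, cycle closure and condition comparison.

An ensemble of n independent simulations of one alchemical transformation
yields n ΔΔG estimates.  The ensemble mean is the reported affinity and the
ensemble standard error — sample sd (n−1 denominator) over √n — is the
reported precision; dividing it by the mean single-run MBAR σ gives the
*precision ratio*, which measures how much a single run overstates its own
reliability.

Cycle closure enumerates every combination of replicate choices around a
closed loop of transformations (signed so the loop returns to its starting
ligand) and summarises the signed sums, which should vanish for converged,
consistent simulations.

:func:`compare_conditions` tests whether two replicate-generation protocols
(for example velocity-seeded vs solvent-box-seeded replicas) produce
different means, with both a seeded Gaussian Monte-Carlo null and the
matching closed-form normal tail.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import re

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "TransformationSummary",
    "CycleDefinition",
    "CycleClosure",
    "ConditionComparison",
    "aggregate_replicates",
    "combine_legs",
    "reverse_transformation",
    "cycle_closure",
    "precision_ratio",
    "compare_conditions",
    "summarize_table",
]

REPLICATE_COLUMNS = [
    "transformation", "condition", "replicate", "ddg_kjmol", "sigma_kjmol",
]


@dataclasses.dataclass(frozen=True)
class TransformationSummary:
    """Ensemble aggregate of one transformation under one condition."""

    transformation: str
    condition: str
    n: int
    mean: float  # kJ/mol
    se: float  # sample sd / sqrt(n), kJ/mol
    mean_sigma_mbar: float  # kJ/mol

    @property
    def precision_ratio(self) -> float:
        return precision_ratio(self)


@dataclasses.dataclass(frozen=True)
class CycleDefinition:
    """Ordered, signed loop of transformations, e.g. L3→L2→L4→L3.

    ``steps`` is a list of (transformation id, sign); a transformation
    traversed against its stored direction carries sign −1.  Transformation
    ids must use the "A->B" (or "A→B") form so closure can be checked.
    """

    steps: tuple[tuple[str, int], ...]

    def __post_init__(self):
        steps = tuple((str(t), int(s)) for t, s in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValueError("a cycle needs at least one step")
        for _, s in steps:
            if s not in (-1, 1):
                raise ValueError("signs must be +1 or -1")
        path = [self._endpoints(t, s) for t, s in steps]
        for (_, end), (start, _) in zip(path, path[1:] + path[:1]):
            if end != start:
                raise ValueError(
                    f"cycle does not close: step ending at '{end}' is "
                    f"followed by a step starting at '{start}'"
                )

    @staticmethod
    def _endpoints(transformation: str, sign: int) -> tuple[str, str]:
        parts = re.split(r"->|→", transformation)
        if len(parts) != 2:
            raise ValueError(
                f"transformation id '{transformation}' is not of the form 'A->B'"
            )
        a, b = (p.strip() for p in parts)
        return (a, b) if sign == 1 else (b, a)


@dataclasses.dataclass(frozen=True)
class CycleClosure:
    """Statistics of the signed free-energy sums around a cycle."""

    cycle: CycleDefinition
    condition: str
    combinations: int
    mean: float
    minimum: float
    maximum: float
    se: float  # quadrature of per-transformation ensemble SEs
    sd_combinations: float  # spread of the enumerated sums


@dataclasses.dataclass(frozen=True)
class ConditionComparison:
    """Two-condition difference with Monte-Carlo and analytic null p-values."""

    transformation: str
    conditions: tuple[str, str]
    n: tuple[int, int]
    difference: float  # mean(B) - mean(A), kJ/mol
    se_difference: float  # sqrt(SE_A^2 + SE_B^2)
    pooled_mean: float
    pooled_sd: float  # sample sd of the combined values
    p_monte_carlo: float
    p_analytic: float
    repetitions: int
    seed: int


def _check_replicates(values: np.ndarray, context: str = "") -> None:
    if values.size < 2:
        raise ValueError(f"at least 2 replicates are required {context}".strip())


def aggregate_replicates(records: pd.DataFrame) -> TransformationSummary:
    """Ensemble mean, SE and mean MBAR σ for one transformation+condition.

    ``records`` must contain a single (transformation, condition) pair with
    unique replicate indices and at least two replicates.
    """
    if records["transformation"].nunique() != 1 or records["condition"].nunique() != 1:
        raise ValueError("aggregate_replicates expects a single transformation+condition")
    if records["replicate"].duplicated().any():
        dup = records.loc[records["replicate"].duplicated(), "replicate"].iloc[0]
        raise ValueError(f"duplicate replicate index {dup!r}")
    values = records["ddg_kjmol"].to_numpy(dtype=float)
    _check_replicates(values, "to form an ensemble SE")
    n = values.size
    return TransformationSummary(
        transformation=str(records["transformation"].iloc[0]),
        condition=str(records["condition"].iloc[0]),
        n=n,
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / math.sqrt(n)),
        mean_sigma_mbar=float(records["sigma_kjmol"].to_numpy(dtype=float).mean()),
    )


def summarize_table(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate every (transformation, condition) group of a replicate table."""
    rows = []
    for (t, c), grp in records.groupby(["transformation", "condition"], sort=False):
        s = aggregate_replicates(grp)
        rows.append(
            (t, c, s.n, s.mean, s.se, s.mean_sigma_mbar,
             s.se / s.mean_sigma_mbar if s.mean_sigma_mbar > 0 else np.nan)
        )
    return pd.DataFrame(
        rows,
        columns=["transformation", "condition", "n", "mean", "se",
                 "mean_sigma_mbar", "precision_ratio"],
    )


def combine_legs(
    bound: tuple[float, float], free: tuple[float, float]
) -> tuple[float, float]:
    """ΔΔG_bind = ΔG_bound − ΔG_free with uncertainties added in quadrature.

    Both legs are (value, σ) in the same units.
    """
    (vb, sb), (vf, sf) = bound, free
    return vb - vf, math.hypot(sb, sf)


def reverse_transformation(value: float, sigma: float) -> tuple[float, float]:
    """Explicit direction reversal: negates ΔΔG, leaves σ unchanged."""
    return -value, sigma


def cycle_closure(
    cycle: CycleDefinition, records: pd.DataFrame, condition: str | None = None
) -> CycleClosure:
    """Closure statistics over the full Cartesian product of replicate choices.

    For a cycle of m transformations with n_i replicates each, all
    Π n_i signed sums are enumerated (lexicographically in replicate index)
    and their count, mean, extrema and spread returned.  The quoted ``se``
    is the quadrature sum of the per-transformation ensemble SEs.
    """
    if condition is not None:
        records = records[records["condition"] == condition]
    rep_values: list[np.ndarray] = []
    ses: list[float] = []
    for name, sign in cycle.steps:
        grp = records[records["transformation"] == name].sort_values("replicate")
        if grp.empty:
            raise ValueError(f"cycle transformation '{name}' has no replicates")
        vals = sign * grp["ddg_kjmol"].to_numpy(dtype=float)
        rep_values.append(vals)
        ses.append(
            float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        )
    sums = np.array(
        [sum(choice) for choice in itertools.product(*rep_values)], dtype=float
    )
    return CycleClosure(
        cycle=cycle,
        condition=condition if condition is not None else "all",
        combinations=int(sums.size),
        mean=float(sums.mean()),
        minimum=float(sums.min()),
        maximum=float(sums.max()),
        se=float(math.sqrt(sum(s * s for s in ses))),
        sd_combinations=float(sums.std(ddof=1)) if sums.size > 1 else 0.0,
    )


def precision_ratio(summary: TransformationSummary) -> float:
    """Ensemble SE over mean per-replicate MBAR σ.

    Values above 1 mean the replicate spread exceeds what a single run's
    internal error estimate suggests.
    """
    if summary.mean_sigma_mbar <= 0:
        raise ValueError("mean MBAR sigma must be positive for a precision ratio")
    return summary.se / summary.mean_sigma_mbar


def compare_conditions(
    records_a: pd.DataFrame | np.ndarray,
    records_b: pd.DataFrame | np.ndarray,
    repetitions: int = 1_000_000,
    seed: int = 20_240_101,
    transformation: str = "",
) -> ConditionComparison:
    """Gaussian-null test of whether two replicate conditions differ.

    The null pools all values (grand mean, pooled sample sd) and asks how
    often two freshly drawn groups of the observed sizes would show a mean
    difference at least as large (in absolute value) as the observed one.
    The Monte-Carlo estimate uses ``repetitions`` seeded draws; the analytic
    p is the matching two-sided normal tail with sd·sqrt(1/n_A + 1/n_B).
    """
    label_a, label_b = "A", "B"
    if isinstance(records_a, pd.DataFrame):
        if "condition" in records_a:
            label_a = str(records_a["condition"].iloc[0])
        records_a = records_a["ddg_kjmol"]
    if isinstance(records_b, pd.DataFrame):
        if "condition" in records_b:
            label_b = str(records_b["condition"].iloc[0])
        records_b = records_b["ddg_kjmol"]
    a = np.asarray(records_a, dtype=float).ravel()
    b = np.asarray(records_b, dtype=float).ravel()
    _check_replicates(a, "in condition A")
    _check_replicates(b, "in condition B")
    if repetitions < 1_000:
        logger.warning(
            "compare_conditions with only %d repetitions: Monte-Carlo p will be noisy",
            repetitions,
        )
    n_a, n_b = a.size, b.size
    diff = float(b.mean() - a.mean())
    se_diff = float(
        math.hypot(a.std(ddof=1) / math.sqrt(n_a), b.std(ddof=1) / math.sqrt(n_b))
    )
    pooled = np.concatenate([a, b])
    mu, sd = float(pooled.mean()), float(pooled.std(ddof=1))

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 200_000
    done = 0
    while done < repetitions:
        m = min(chunk, repetitions - done)
        ga = rng.normal(mu, sd, size=(m, n_a)).mean(axis=1)
        gb = rng.normal(mu, sd, size=(m, n_b)).mean(axis=1)
        hits += int(np.count_nonzero(np.abs(gb - ga) >= abs(diff)))
        done += m
    p_mc = hits / repetitions

    null_sd = sd * math.sqrt(1.0 / n_a + 1.0 / n_b)
    p_an = 1.0 if null_sd == 0 and diff == 0 else float(
        2.0 * norm.sf(abs(diff) / null_sd) if null_sd > 0 else 0.0
    )
    return ConditionComparison(
        transformation=transformation,
        conditions=(label_a, label_b),
        n=(n_a, n_b),
        difference=diff,
        se_difference=se_diff,
        pooled_mean=mu,
        pooled_sd=sd,
        p_monte_carlo=p_mc,
        p_analytic=p_an,
        repetitions=repetitions,
        seed=seed,
    )
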