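"""CSV/JSON formats and the end-to-end study workflow.

File formats
------------
* Replicate table (CSV): header
  ``transformation,condition,replicate,ddg_kjmol,sigma_kjmol``.
* Reduced-potential table (CSV, "u_nk" layout): one row per sample; first
  column ``state`` is the integer index of the state the sample was drawn
  from, remaining columns are the sample's reduced potential evaluated at
  every λ, with the λ value itself as the column header.
* Experimental reference table (CSV): header
  ``transformation,exp,exp_bound,exp_sigma`` (last two optional).
* Cycle definitions (JSON): mapping name → list of [transformation, sign].

:func:`run_study` chains aggregation, precision ratios, cycle closure,
quality metrics and per-transformation condition comparison into one
deterministic JSON-serialisable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_analysis import (
    REPLICATE_COLUMNS,
    CycleDefinition,
    aggregate_replicates,
    compare_conditions,
    cycle_closure,
    summarize_table,
)
from .estimators import ReducedPotentialSet
from .quality_metrics import PredictionSet, bootstrap_quality

logger = logging.getLogger(__name__)

__all__ = [
    "read_replicates",
    "write_replicates",
    "read_u_nk",
    "write_u_nk",
    "read_experimental",
    "read_cycles",
    "run_study",
    "SchemaError",
]


class SchemaError(ValueError):
    """A tabular input violated its schema; carries itemised row errors."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        super().__init__(
            f"{path}: {len(problems)} schema problem(s):\n  " + "\n  ".join(problems)
        )


def read_replicates(path) -> pd.DataFrame:
    """Read and validate a replicate ΔΔG table.

    Malformed rows are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing column(s) {missing}"])
    if df.empty:
        logger.warning("%s: header-only replicate table (no records)", path)
        return df
    problems = []
    lines = df.index + 2  # header is line 1
    for col in ("ddg_kjmol", "sigma_kjmol"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for ln in lines[vals.isna() & df[col].notna()]:
            problems.append(f"line {ln}: non-numeric {col}")
        df[col] = vals
    bad_sigma = df["sigma_kjmol"] < 0
    for ln in lines[bad_sigma.fillna(False)]:
        problems.append(f"line {ln}: negative sigma_kjmol")
    dup = df.duplicated(subset=["transformation", "condition", "replicate"])
    for ln in lines[dup]:
        problems.append(f"line {ln}: duplicate (transformation, condition, replicate)")
    if problems:
        raise SchemaError(path, problems)
    return df


def write_replicates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=REPLICATE_COLUMNS)


def write_u_nk(data: ReducedPotentialSet, path) -> None:
    """Write a reduced-potential set in the u_nk CSV layout."""
    lam = (
        data.lambdas
        if data.lambdas is not None
        else np.linspace(0.0, 1.0, data.n_states)
    )
    state_idx = np.repeat(np.arange(data.n_states), data.n_k)
    out = pd.DataFrame(data.u_kn.T, columns=[repr(float(l)) for l in lam])
    out.insert(0, "state", state_idx)
    out.to_csv(path, index=False)


def read_u_nk(path) -> ReducedPotentialSet:
    """Read a u_nk CSV back into a :class:`ReducedPotentialSet`.

    Samples are regrouped by their sampling-state index; the λ schedule is
    parsed from the column headers.
    """
    df = pd.read_csv(path)
    if "state" not in df.columns:
        raise SchemaError(path, ["missing 'state' column"])
    try:
        lam = np.array([float(c) for c in df.columns if c != "state"])
    except ValueError as exc:
        raise SchemaError(path, [f"non-numeric lambda column header: {exc}"]) from exc
    if np.any(np.diff(lam) <= 0):
        raise SchemaError(path, ["lambda columns must be strictly increasing"])
    states = df["state"].to_numpy()
    if not np.issubdtype(states.dtype, np.integer):
        raise SchemaError(path, ["state column must be integer"])
    k = lam.size
    if states.min() < 0 or states.max() >= k:
        raise SchemaError(path, ["state index outside the lambda schedule"])
    u = df.drop(columns="state").to_numpy(dtype=float)
    if not np.all(np.isfinite(u)):
        raise SchemaError(path, ["non-finite reduced potential"])
    order = np.argsort(states, kind="stable")
    n_k = np.bincount(states, minlength=k)
    return ReducedPotentialSet(u_kn=u[order].T, n_k=n_k, lambdas=lam)


def read_experimental(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "transformation" not in df.columns or "exp" not in df.columns:
        raise SchemaError(path, ["need columns 'transformation' and 'exp'"])
    if "exp_bound" not in df.columns:
        df["exp_bound"] = False
    df["exp_bound"] = df["exp_bound"].fillna(False).astype(bool)
    if "exp_sigma" not in df.columns:
        df["exp_sigma"] = np.nan
    return df


def read_cycles(path) -> dict[str, CycleDefinition]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        name: CycleDefinition(tuple((t, int(s)) for t, s in steps))
        for name, steps in raw.items()
    }


def _derive_seed(seed: int, stage: int) -> int:
    """Per-stage child seed, kept below 2^31."""
    return int((seed * 1_000_003 + stage) % (2**31 - 1))


def run_study(
    replicates: pd.DataFrame,
    experimental: pd.DataFrame | None = None,
    cycles: dict[str, CycleDefinition] | None = None,
    seed: int = 0,
    mc_repetitions: int = 1_000_000,
    bootstrap_sets: int = 1000,
    significance_multiple: float = 2.0,
) -> dict:
    """Full ensemble analysis of a two-condition replicate study.

    Returns a JSON-serialisable report with, per transformation+condition,
    the ensemble summary and precision ratio; per cycle+condition the
    closure statistics; per condition the quality report against
    experiment (when an experimental table is given); and per
    transformation the two-condition comparison (when exactly two
    conditions are present), flagged significant when the observed
    difference exceeds ``significance_multiple`` times its SE.
    """
    report: dict = {"seed": seed, "stage_seeds": {}}
    summary = summarize_table(replicates)
    report["summaries"] = summary.to_dict(orient="records")

    conditions = list(dict.fromkeys(replicates["condition"]))

    if cycles:
        cyc_out = []
        for name, cyc in cycles.items():
            for cond in conditions:
                c = cycle_closure(cyc, replicates, condition=cond)
                cyc_out.append(
                    {
                        "cycle": name,
                        "condition": cond,
                        "combinations": c.combinations,
                        "mean": c.mean,
                        "min": c.minimum,
                        "max": c.maximum,
                        "se": c.se,
                        "sd_combinations": c.sd_combinations,
                    }
                )
        report["cycles"] = cyc_out

    if experimental is not None and len(experimental):
        qual_out = {}
        for i, cond in enumerate(conditions):
            sub = summary[summary["condition"] == cond]
            merged = sub.merge(experimental, on="transformation", how="inner")
            if len(merged) < 2:
                continue
            pset = PredictionSet.from_arrays(
                merged["transformation"],
                merged["mean"],
                merged["se"],
                merged["exp"],
                exp_bound=merged["exp_bound"],
                exp_sigma=merged["exp_sigma"],
            )
            qseed = _derive_seed(seed, 100 + i)
            report["stage_seeds"][f"quality_{cond}"] = qseed
            qual_out[cond] = bootstrap_quality(
                pset, sets=bootstrap_sets, seed=qseed
            ).to_dict()
        report["quality"] = qual_out

    if len(conditions) == 2:
        comp_out = []
        cond_a, cond_b = conditions
        for j, t in enumerate(dict.fromkeys(replicates["transformation"])):
            sub = replicates[replicates["transformation"] == t]
            a = sub[sub["condition"] == cond_a]
            b = sub[sub["condition"] == cond_b]
            if len(a) < 2 or len(b) < 2:
                continue
            cseed = _derive_seed(seed, 200 + j)
            report["stage_seeds"][f"compare_{t}"] = cseed
            comp = compare_conditions(
                a, b, repetitions=mc_repetitions, seed=cseed, transformation=t
            )
            d = dataclasses.asdict(comp)
            d["significant"] = bool(
                abs(comp.difference) >= significance_multiple * comp.se_difference
            )
            comp_out.append(d)
        report["comparisons"] = comp_out

    return report


def write_report(report: dict, out_dir, stem: str = "study") -> None:
    """Emit a run_study report as JSON plus per-section CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    for section in ("summaries", "cycles", "comparisons"):
        if section in report and report[section]:
            pd.DataFrame(report[section]).to_csv(
                out / f"{stem}_{section}.csv", index=False
            )
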