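import numpy as np
import pytest

import fepensemble as fe


@pytest.fixture(scope="session")
def brd4():
    return fe.fixtures.load_brd4()


@pytest.fixture(scope="session")
def lysozyme():
    return fe.fixtures.load_lysozyme()


@pytest.fixture(scope="session")
def harmonic_pair():
    """Two-state harmonic ladder with exact Δf = ½ ln 4, plus its MBAR solution."""
    spec = fe.HarmonicSchedule(
        stiffness=[1.0, 4.0], offsets=[0.0, 0.0], samples_per_state=20_000, seed=42
    )
    data, exact = fe.gen_harmonic_alchemy(spec)
    return data, exact, fe.mbar_solve(data)


@pytest.fixture(scope="session")
def lysozyme_predictions(lysozyme):
    """PredictionSets (calc vs exp) for both conditions of the lysozyme study."""
    summary = fe.summarize_table(lysozyme.replicates)
    out = {}
    for cond in ("VIS", "SIS"):
        s = summary[summary["condition"] == cond].merge(
            lysozyme.experimental, on="transformation"
        )
        out[cond] = fe.PredictionSet.from_arrays(
            s["transformation"], s["mean"], s["se"], s["exp"],
            exp_bound=s["exp_bound"], exp_sigma=s["exp_sigma"],
        )
    return out


def assert_printed(value, printed, decimals):
    """Match a recomputed value against a published table entry.

    Published entries are rounded to ``decimals``; allow one unit in the
    last printed digit to absorb the source's own rounding.
    """
    unit = 10.0 ** (-decimals)
    assert abs(value - printed) <= unit + 1e-12, (
        f"{value:.4f} differs from printed {printed} by more than {unit}"
    )
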