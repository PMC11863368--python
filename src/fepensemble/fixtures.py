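"""Packaged replicate-study fixtures.

Two published five-replicate, two-condition (velocity-seeded vs
solvent-seeded) relative binding free-energy studies ship with the
package as plain CSV: a four-transformation bromodomain study and a
six-transformation T4-lysozyme L99A study, each with per-replicate MBAR
precisions, experimental reference affinities and a three-transformation
thermodynamic cycle.  Every value is a transcribed table cell from the
source study; nothing is simulated here.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

from .ensemble_analysis import CycleDefinition
from .io import read_cycles, read_experimental, read_replicates

__all__ = ["StudyFixture", "load_brd4", "load_lysozyme"]


@dataclasses.dataclass(frozen=True)
class StudyFixture:
    name: str
    replicates: pd.DataFrame
    experimental: pd.DataFrame
    cycle: CycleDefinition


def _data_path(filename: str):
    return resources.files("fepensemble.data").joinpath(filename)


def _load(name: str, replicate_file: str, experimental_file: str) -> StudyFixture:
    with resources.as_file(_data_path(replicate_file)) as p:
        reps = read_replicates(p)
    with resources.as_file(_data_path(experimental_file)) as p:
        exp = read_experimental(p)
    with resources.as_file(_data_path("cycles.json")) as p:
        cycles = read_cycles(p)
    return StudyFixture(
        name=name, replicates=reps, experimental=exp, cycle=cycles[name]
    )


def load_brd4() -> StudyFixture:
    """Bromodomain study: 4 transformations x 2 conditions x 5 replicates."""
    return _load("brd4", "brd4_replicates.csv", "brd4_experimental.csv")


def load_lysozyme() -> StudyFixture:
    """T4-lysozyme L99A study: 6 transformations x 2 conditions x 5 replicates.

    The experimental value for the first transformation is a lower bound
    (flagged in the table) and is used at face value by the quality
    metrics.
    """
    return _load("lysozyme", "lysozyme_replicates.csv", "lysozyme_experimental.csv")
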