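"""Prey habitat associations and predator × habitat independence test.

Prey taxa are classified as habitat generalists, grassland specialists,
or woodland specialists from a user-supplied lookup table (compiled
from field guides; treated as data, not code).  The question of
interest is whether which predator consumed a prey taxon is independent
of that taxon's habitat class — tested with a Pearson chi-square on the
(habitat class × predator) contingency table of distinct prey taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diet import UtilizationMatrix

HABITAT_CLASSES = (
    "generalist",
    "grassland_specialist",
    "woodland_specialist",
    "unknown",
)
SPECIALIST_CLASSES = ("grassland_specialist", "woodland_specialist")


class HabitatTable(dict):
    """Mapping of prey taxon -> habitat class (closed vocabulary)."""

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        super().__init__()
        for taxon, cls in (mapping or {}).items():
            self[taxon] = cls

    def __setitem__(self, taxon: str, cls: str) -> None:
        if cls not in HABITAT_CLASSES:
            raise ValueError(
                f"habitat class {cls!r} not in {HABITAT_CLASSES}"
            )
        super().__setitem__(taxon, cls)

    def classify(self, taxon: str) -> str:
        return self.get(taxon, "unknown")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HabitatTable":
        table = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, habitat = line.split("\t")[:2]
            table[taxon] = habitat
        if not table:
            raise ValueError(f"habitat table {path} is empty")
        return table


def classify_diet(
    matrix: UtilizationMatrix,
    habitat: HabitatTable,
    specialists_only: bool = True,
) -> pd.DataFrame:
    """Contingency table of distinct prey taxa per (habitat class, predator).

    A taxon consumed by several predators increments every one of their
    columns.  With ``specialists_only`` (default), generalists and
    unclassified taxa are dropped; an empty table after filtering is an
    error.
    """
    classes = SPECIALIST_CLASSES if specialists_only else HABITAT_CLASSES
    table = pd.DataFrame(0, index=list(classes), columns=matrix.predators)
    for resource in matrix.resources:
        cls = habitat.classify(resource)
        if cls not in classes:
            continue
        for predator in matrix.predators:
            if matrix.data.at[resource, predator] > 0:
                table.at[cls, predator] += 1
    if int(table.to_numpy().sum()) == 0:
        raise ValueError(
            "no prey taxa left after habitat filtering; cannot build a table"
        )
    return table


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    yates: bool


def chi_square_independence(
    table: pd.DataFrame | np.ndarray, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    ``yates`` applies the continuity correction (2×2 tables only, per
    the usual convention).
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or min(observed.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(observed.sum(axis=0) == 0) or np.any(observed.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(observed, correction=yates)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=np.asarray(res.expected_freq),
        yates=yates,
    )
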