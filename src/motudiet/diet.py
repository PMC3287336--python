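"""Dietary descriptors on predator × resource utilization matrices.

The central object is the utilization matrix: rows are resources (MOTUs
or named prey taxa), columns are predator species, and each cell counts
the fecal samples of that predator in which the resource occurred.
Occurrence counts — not read counts — are the unit of quantification,
because amplicon abundance within a sample is not a reliable measure of
how much was eaten.

From a predator's occurrence-count vector we compute:

* Levins' niche breadth ``B = 1 / sum(p_i^2)`` and its standardized
  form ``B_A = (B - 1) / (n - 1)`` in [0, 1],
* Shannon diversity ``H = -sum(p_i ln p_i)``,
* Pianka's niche overlap between two predators,
  ``O_jk = sum(P_ij P_ik) / sqrt(sum(P_ij^2) sum(P_ik^2))``,

where ``p_i`` (``P_ij``) is resource *i*'s share of all occurrences for
that predator, i.e. counts normalized to sum to 1.  All three are
invariant to rescaling the count vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("order", "family", "species", "confidence")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going up, the convention used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class UtilizationMatrix:
    """Predator × resource occurrence-count matrix.

    Parameters
    ----------
    data:
        DataFrame with one row per resource (index = resource labels)
        and one integer column per predator.
    annotations:
        Optional DataFrame aligned on the same index carrying ``order``
        and ``family`` labels (plus any extra columns, e.g. an
        identification confidence level).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        annotations: pd.DataFrame | None = None,
    ) -> None:
        counts = data.to_numpy()
        if counts.size:
            if np.any(counts < 0):
                raise ValueError("occurrence counts must be non-negative")
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("occurrence counts must be integers")
        self.data = data.astype(int)
        if not self.data.index.is_unique:
            raise ValueError("resource labels must be unique")
        if annotations is not None:
            annotations = annotations.reindex(self.data.index)
        self.annotations = annotations

    # -- basic accessors ---------------------------------------------------
    @property
    def predators(self) -> list[str]:
        return list(self.data.columns)

    @property
    def resources(self) -> list[str]:
        return list(self.data.index)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def column(self, predator: str) -> np.ndarray:
        if predator not in self.data.columns:
            raise KeyError(f"unknown predator {predator!r}")
        return self.data[predator].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UtilizationMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"UtilizationMatrix({len(self.resources)} resources x "
            f"{len(self.predators)} predators)"
        )

    # -- derived views -----------------------------------------------------
    def orders_used(self, predator: str) -> list[str]:
        """Distinct prey orders with at least one occurrence for a predator."""
        if self.annotations is None or "order" not in self.annotations:
            raise ValueError("matrix has no order annotations")
        mask = self.column(predator) > 0
        return sorted(self.annotations.loc[mask, "order"].dropna().unique())

    def with_predators(self, predators: Sequence[str]) -> "UtilizationMatrix":
        sub = self.data[list(predators)]
        keep = sub.sum(axis=1) > 0
        ann = self.annotations.loc[keep] if self.annotations is not None else None
        return UtilizationMatrix(sub.loc[keep], ann)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.annotations is not None:
            for col in reversed(self.annotations.columns):
                out.insert(0, col, self.annotations[col])
        out.index.name = "resource"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UtilizationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="resource")
        # any non-numeric column is annotation, not counts
        ann_cols = [
            c for c in df.columns
            if c in ANNOTATION_COLUMNS or not pd.api.types.is_numeric_dtype(df[c])
        ]
        annotations = df[ann_cols] if ann_cols else None
        counts = df.drop(columns=ann_cols)
        return cls(counts, annotations)


def build_matrix(
    presence: Mapping[tuple[Hashable, str], Iterable[str]],
    annotations: pd.DataFrame | None = None,
) -> UtilizationMatrix:
    """Build a utilization matrix from per-sample resource sets.

    ``presence`` maps ``(sample_id, predator)`` to the set of resources
    found in that sample; each sample belongs to exactly one predator.
    ``counts[i, j]`` is the number of predator *j*'s samples containing
    resource *i*.  Resources never observed are absent (no all-zero
    rows by construction).
    """
    samples_seen: dict[Hashable, str] = {}
    predators: list[str] = []
    tallies: dict[str, dict[str, int]] = {}
    for (sample, predator), resources in presence.items():
        if samples_seen.setdefault(sample, predator) != predator:
            raise ValueError(f"sample {sample!r} is assigned to two predators")
        if predator not in predators:
            predators.append(predator)
        for res in set(resources):
            tallies.setdefault(res, {}).setdefault(predator, 0)
            tallies[res][predator] += 1
    data = pd.DataFrame(
        {p: {r: tallies[r].get(p, 0) for r in sorted(tallies)} for p in predators},
        dtype=int,
    )
    if data.empty:
        data = pd.DataFrame(columns=predators, dtype=int)
    return UtilizationMatrix(data, annotations)


@dataclass
class NicheDescriptors:
    """Levins breadth and Shannon diversity of one predator's diet."""

    levins_B: float
    levins_BA: float
    shannon_H: float
    n_resources: int


@dataclass
class SampleSummary:
    """Distribution of per-sample resource richness."""

    per_sample_counts: list[int]
    mean: float
    sd: float
    min: int
    max: int


def _proportions(counts: Sequence[float]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one count must be positive")
    return c / total


def levins_breadth(
    counts: Sequence[float], n_resources: int | None = None
) -> tuple[float, float]:
    """Levins' niche breadth ``B`` and standardized breadth ``B_A``.

    ``n_resources`` is the number of possible resource states; it
    defaults to the number of resources actually used, which makes
    ``B_A`` a within-diet evenness measure.  Pass the global resource
    pool size to standardize against all available resources instead.
    """
    p = _proportions(counts)
    used = int(np.count_nonzero(p))
    if n_resources is None:
        n_resources = used
    if n_resources < used:
        raise ValueError("n_resources cannot be smaller than the resources used")
    b = 1.0 / float(np.sum(p**2))
    ba = 0.0 if n_resources == 1 else (b - 1.0) / (n_resources - 1.0)
    return b, ba


def shannon_diversity(counts: Sequence[float]) -> float:
    """Shannon diversity ``H = -sum(p ln p)`` over positive proportions."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def niche_descriptors(
    counts: Sequence[float], n_resources: int | None = None
) -> NicheDescriptors:
    b, ba = levins_breadth(counts, n_resources)
    h = shannon_diversity(counts)
    n = int(np.count_nonzero(np.asarray(counts))) if n_resources is None else n_resources
    return NicheDescriptors(levins_B=b, levins_BA=ba, shannon_H=h, n_resources=n)


def pianka_overlap(counts_j: Sequence[float], counts_k: Sequence[float]) -> float:
    """Pianka's niche-overlap index between two predators.

    Both vectors must index the same resources in the same order.
    Symmetric, in [0, 1], and invariant to rescaling either vector.
    """
    pj = _proportions(counts_j)
    pk = _proportions(counts_k)
    if pj.shape != pk.shape:
        raise ValueError("count vectors must have equal length")
    denom = np.sqrt(np.sum(pj**2) * np.sum(pk**2))
    return float(np.dot(pj, pk) / denom)


def percent_fo_by_order(
    matrix: UtilizationMatrix,
    predator: str,
    sample_order_presence: Mapping[Hashable, Iterable[str]],
) -> dict[str, float]:
    """Percent frequency of occurrence (%FO) of prey orders.

    For each order: 100 × (number of samples containing the order) /
    (total occurrences of all orders across samples).  Values sum to
    100 up to floating-point error.
    """
    matrix.column(predator)  # validates the predator exists
    order_counts: dict[str, int] = {}
    for orders in sample_order_presence.values():
        for order in set(orders):
            order_counts[order] = order_counts.get(order, 0) + 1
    total = sum(order_counts.values())
    if total == 0:
        raise ValueError(f"predator {predator!r} has no order occurrences")
    return {o: 100.0 * n / total for o, n in sorted(order_counts.items())}


def family_share(
    matrix: UtilizationMatrix, predator: str, order: str, family: str
) -> float:
    """A family's percentage of one order's occurrences for a predator.

    Rounded to one decimal place (half-up), the convention used for
    reported diet percentages.
    """
    if matrix.annotations is None:
        raise ValueError("matrix has no order/family annotations")
    col = matrix.data[predator] if predator in matrix.data else None
    if col is None:
        raise KeyError(f"unknown predator {predator!r}")
    ann = matrix.annotations
    in_order = ann["order"] == order
    order_total = int(col[in_order].sum())
    if order_total == 0:
        raise ValueError(f"order {order!r} has no occurrences for {predator!r}")
    fam_total = int(col[in_order & (ann["family"] == family)].sum())
    return round_half_up(100.0 * fam_total / order_total, 1)


def sample_summary(
    presence: Mapping[Hashable, Iterable[str]], ddof: int = 1
) -> SampleSummary:
    """Per-sample resource richness: mean, SD (sample convention by
    default), minimum and maximum."""
    if not presence:
        raise ValueError("no samples to summarise")
    counts = [len(set(r)) for r in presence.values()]
    arr = np.asarray(counts)
    sd = 0.0 if len(arr) <= ddof else float(arr.std(ddof=ddof))
    return SampleSummary(
        per_sample_counts=counts,
        mean=float(arr.mean()),
        sd=sd,
        min=int(arr.min()),
        max=int(arr.max()),
    )
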