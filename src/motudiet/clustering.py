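"""MOTU clustering by single linkage on pairwise alignment distance.

Haplotypes are collapsed into Molecular Operational Taxonomic Units
(MOTUs) — connected components of the graph that links any two
haplotypes whose p-distance is at or below a divergence threshold.
Single linkage makes the partitions nested: raising the threshold can
only merge MOTUs, never split them, so the MOTU count is non-increasing
across a threshold sweep.  The working threshold is read off the sweep
curve at its inflection point: the first threshold where the count
stops dropping (new MOTUs no longer appear) but clusters have not yet
begun to collapse into each other.

Distances are p-distances on an optimal global (Needleman–Wunsch)
pairwise alignment with unit mismatch/gap costs and free end gaps:
mismatches plus internal gaps, divided by the number of alignment
columns between the first and last column where both sequences have a
base.  For equal-length ungapped alignments this reduces to the Hamming
fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .amplicon import Haplotype

#: distances are rounded to this many decimals before threshold
#: comparison, to keep <= decisions stable at grid boundaries
DISTANCE_DECIMALS = 6

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -1.0
# end gaps are free: terminal overhangs are not divergence
try:
    _aligner.end_insertion_score = 0.0
    _aligner.end_deletion_score = 0.0
except AttributeError:  # biopython < 1.86 spelling
    _aligner.target_end_gap_score = 0.0
    _aligner.query_end_gap_score = 0.0


def pairwise_distance(a: str, b: str) -> float:
    """p-distance between two sequences under end-gap-free global alignment.

    Symmetric, 0 iff the sequences are identical, and at most 1.
    """
    if not a or not b:
        raise ValueError("cannot compute a distance involving an empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 0.0
    if b < a:
        # co-optimal alignments can differ between argument orders;
        # canonicalising the order makes the distance exactly symmetric
        a, b = b, a
    aln = _aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    n = len(s1)
    lo = 0
    while lo < n and ("-" in (s1[lo], s2[lo])):
        lo += 1
    hi = n
    while hi > lo and ("-" in (s1[hi - 1], s2[hi - 1])):
        hi -= 1
    core = hi - lo
    bad = sum(1 for i in range(lo, hi) if s1[i] != s2[i])
    if core == 0 or bad == 0:
        # distinct sequences whose aligned core is identical (pure
        # overhangs); attribute the difference to the end columns so
        # the 0-iff-identical contract holds
        extra = n - core
        return extra / n
    return bad / core


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances between haplotypes."""

    haplotype_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.haplotype_ids), len(self.haplotype_ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if d.size and (d.min() < 0 or d.max() > 1):
            raise ValueError("distances must lie in [0, 1]")
        self.distances = d

    @classmethod
    def from_sequences(
        cls, ids: Sequence[str], sequences: Sequence[str]
    ) -> "DistanceMatrix":
        n = len(sequences)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_distance(sequences[i], sequences[j])
        return cls(list(ids), d)

    @classmethod
    def from_haplotypes(cls, haplotypes: Sequence[Haplotype]) -> "DistanceMatrix":
        return cls.from_sequences(
            [h.haplotype_id for h in haplotypes], [h.sequence for h in haplotypes]
        )

    def __len__(self) -> int:
        return len(self.haplotype_ids)


@dataclass
class MOTUCluster:
    """One MOTU: a set of haplotypes linked at a divergence threshold."""

    motu_id: str
    member_haplotypes: set[str]
    threshold: float
    representatives: list[str] = field(default_factory=list)
    per_sample_presence: set[str] = field(default_factory=set)
    total_abundance: int = 0

    def __post_init__(self) -> None:
        if not self.member_haplotypes:
            raise ValueError("a MOTU must contain at least one haplotype")


@dataclass
class ThresholdSweep:
    """MOTU counts across a grid of divergence thresholds."""

    thresholds: list[float]
    motu_counts: list[int]
    selected_threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.motu_counts):
            raise ValueError("thresholds and counts differ in length")
        if any(
            c2 > c1 for c1, c2 in zip(self.motu_counts, self.motu_counts[1:])
        ):
            raise ValueError("MOTU counts must be non-increasing in the threshold")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["threshold\tmotu_count"]
        lines += [f"{t:g}\t{c}" for t, c in zip(self.thresholds, self.motu_counts)]
        Path(path).write_text("\n".join(lines) + "\n")


def _component_labels(dm: DistanceMatrix, threshold: float) -> np.ndarray:
    d = np.round(dm.distances, DISTANCE_DECIMALS)
    adjacency = csr_matrix(d <= round(threshold, DISTANCE_DECIMALS))
    _, labels = connected_components(adjacency, directed=False)
    return labels


def cluster_at_threshold(
    dm: DistanceMatrix,
    threshold: float,
    haplotypes: Mapping[str, Haplotype] | None = None,
) -> list[MOTUCluster]:
    """Partition haplotypes into MOTUs at one divergence threshold.

    Clusters are the connected components of the graph with an edge
    wherever distance <= threshold.  MOTU ids are assigned
    deterministically by (cluster size descending, lexicographically
    smallest member sequence — or smallest member id when sequences are
    unavailable).  If ``haplotypes`` is given, representatives (the up
    to three most abundant member haplotypes) and per-sample presence
    are filled in.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if len(dm) == 0:
        return []
    labels = _component_labels(dm, threshold)
    groups: dict[int, list[str]] = {}
    for hid, lab in zip(dm.haplotype_ids, labels):
        groups.setdefault(int(lab), []).append(hid)

    def sort_key(members: list[str]):
        if haplotypes is not None:
            key = min(haplotypes[m].sequence for m in members)
        else:
            key = min(members)
        return (-len(members), key)

    clusters = []
    for rank, members in enumerate(sorted(groups.values(), key=sort_key)):
        cluster = MOTUCluster(
            motu_id=f"MOTU_{rank + 1:04d}",
            member_haplotypes=set(members),
            threshold=threshold,
        )
        if haplotypes is not None:
            cluster.representatives = pick_representatives(
                cluster.member_haplotypes, haplotypes
            )
            cluster.total_abundance = sum(
                haplotypes[m].total_abundance for m in members
            )
            for m in members:
                cluster.per_sample_presence |= set(
                    haplotypes[m].per_sample_abundance
                )
        clusters.append(cluster)
    return clusters


def pick_representatives(
    members: set[str], haplotypes: Mapping[str, Haplotype], k: int = 3
) -> list[str]:
    """The up-to-``k`` most abundant member sequences, ties broken
    lexicographically by sequence."""
    if not members:
        raise ValueError("cannot pick representatives from an empty cluster")
    ranked = sorted(
        (haplotypes[m] for m in members),
        key=lambda h: (-h.total_abundance, h.sequence),
    )
    return [h.sequence for h in ranked[:k]]


def sweep_thresholds(
    dm: DistanceMatrix,
    start: float = 0.0,
    stop: float = 0.10,
    step: float = 0.005,
) -> ThresholdSweep:
    """Count MOTUs at every threshold on a [start, stop] grid."""
    if not (0 <= start < stop <= 1):
        raise ValueError("need 0 <= start < stop <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round((stop - start) / step))
    thresholds = [round(start + i * step, DISTANCE_DECIMALS) for i in range(n_steps + 1)]
    if thresholds[-1] > stop + 1e-12:
        thresholds.pop()
    d = np.round(dm.distances, DISTANCE_DECIMALS)
    counts = []
    for t in thresholds:
        adjacency = csr_matrix(d <= t)
        n_comp, _ = connected_components(adjacency, directed=False)
        counts.append(int(n_comp))
    return ThresholdSweep(thresholds, counts)


def select_infliction_threshold(
    sweep: ThresholdSweep, plateau_tolerance: int = 0
) -> float:
    """Pick the working threshold at the sweep curve's inflection point.

    Returns the smallest threshold whose MOTU count drops by at most
    ``plateau_tolerance`` to the next grid point, *after* the curve has
    begun to drop — the start of the plateau where distinct haplotypes
    of one taxon have merged but taxa have not yet collapsed into each
    other.  (Sweep curves are typically flat over the first grid steps
    too, below the smallest observed distance; that leading segment is
    not the plateau of interest.)  A curve that is constant everywhere
    returns the first threshold; a curve that never plateaus returns
    the last threshold with a warning.
    """
    if len(sweep.thresholds) < 3:
        raise ValueError("a sweep needs at least 3 thresholds")
    counts = sweep.motu_counts
    if counts[0] == counts[-1]:
        sweep.selected_threshold = sweep.thresholds[0]
        return sweep.thresholds[0]
    dropped = False
    for i in range(len(sweep.thresholds) - 1):
        step_drop = counts[i] - counts[i + 1]
        if dropped and step_drop <= plateau_tolerance:
            sweep.selected_threshold = sweep.thresholds[i]
            return sweep.thresholds[i]
        if step_drop > plateau_tolerance:
            dropped = True
    warnings.warn(
        "MOTU count never plateaued across the sweep; falling back to the "
        "largest threshold",
        stacklevel=2,
    )
    sweep.selected_threshold = sweep.thresholds[-1]
    return sweep.thresholds[-1]


def write_motu_table(clusters: Sequence[MOTUCluster], path: str | Path) -> None:
    lines = ["motu_id\tthreshold\tn_haplotypes\ttotal_abundance\tsamples"]
    for c in clusters:
        lines.append(
            f"{c.motu_id}\t{c.threshold:g}\t{len(c.member_haplotypes)}\t"
            f"{c.total_abundance}\t{','.join(sorted(c.per_sample_presence))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_representatives_fasta(
    clusters: Sequence[MOTUCluster],
    haplotypes: Mapping[str, Haplotype],
    path: str | Path,
) -> None:
    abundance = {h.sequence: h.total_abundance for h in haplotypes.values()}
    lines = []
    for c in clusters:
        for rank, seq in enumerate(c.representatives, start=1):
            lines.append(f">{c.motu_id}|{rank}|{abundance.get(seq, 0)}")
            lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")
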