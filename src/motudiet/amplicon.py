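"""Amplicon read handling: demultiplexing, filtering, dereplication.

Pooled amplicon runs carry a sample-identifying MID tag and the PCR
primer at the 5' end of every read.  Reads are assigned back to samples
by exact tag+primer prefix match (any mismatch in the prefix discards
the read), trimmed, length-filtered, collapsed into unique haplotypes,
and purged of singletons (haplotypes seen exactly once in the run),
which are overwhelmingly likely to be sequencing errors.

The stage order is fixed: demultiplex -> length filter -> dereplicate
-> singleton removal.  Read counts are conserved across the chain and
reported in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass
class TaggedRead:
    """A single sequencing read, possibly still carrying tag+primer."""

    read_id: str
    sequence: str
    assigned_sample: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass
class Haplotype:
    """A dereplicated unique sequence with its abundance."""

    haplotype_id: str
    sequence: str
    total_abundance: int
    per_sample_abundance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_abundance < 1:
            raise ValueError("haplotype abundance must be >= 1")
        if self.per_sample_abundance and (
            sum(self.per_sample_abundance.values()) != self.total_abundance
        ):
            raise ValueError(
                "per-sample abundances do not sum to the total abundance"
            )


@dataclass
class FilterReport:
    """Read accounting across the filter chain.

    The conservation identity ``input_reads = retained + discards`` is
    enforced on construction via :meth:`validate`.
    """

    input_reads: int = 0
    discarded_primer_mismatch: int = 0
    discarded_short: int = 0
    discarded_singletons: int = 0
    retained: int = 0

    def validate(self) -> None:
        total = (
            self.retained
            + self.discarded_primer_mismatch
            + self.discarded_short
            + self.discarded_singletons
        )
        if total != self.input_reads:
            raise ValueError(
                f"filter report does not conserve reads: input={self.input_reads}, "
                f"accounted={total}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def demultiplex(
    reads: Iterable[TaggedRead],
    tag_map: Mapping[str, str],
    primer: str,
) -> tuple[list[TaggedRead], FilterReport]:
    """Assign reads to samples by exact 5' tag+primer match and trim.

    A read is assigned iff its prefix is exactly ``tag + primer`` for
    some tag in ``tag_map``; the prefix is then removed.  Everything
    else (including reads with a single substitution or an N anywhere
    in the tag/primer region) counts as a primer-mismatch discard.
    """
    if not tag_map:
        raise ValueError("tag_map is empty: nothing to demultiplex against")
    lengths = {len(t) for t in tag_map}
    if len(lengths) != 1:
        raise ValueError(f"tags must have equal length, got lengths {sorted(lengths)}")
    if len(set(tag_map.values())) != len(tag_map):
        # two tags pointing at the same sample is fine; the reverse is
        # impossible with a dict, but sample collisions are suspicious
        logger.warning("multiple tags map to the same sample")
    tag_len = lengths.pop()
    primer = primer.upper()
    plen = len(primer)

    assigned: list[TaggedRead] = []
    report = FilterReport()
    for read in reads:
        report.input_reads += 1
        seq = read.sequence
        sample = tag_map.get(seq[:tag_len])
        if sample is not None and seq[tag_len : tag_len + plen] == primer and len(
            seq
        ) > tag_len + plen:
            assigned.append(
                TaggedRead(read.read_id, seq[tag_len + plen :], assigned_sample=sample)
            )
        else:
            report.discarded_primer_mismatch += 1
    report.retained = len(assigned)
    report.validate()
    logger.info(
        "demultiplex: %d reads in, %d assigned, %d primer/tag mismatches",
        report.input_reads,
        report.retained,
        report.discarded_primer_mismatch,
    )
    return assigned, report


def length_filter(
    reads: Iterable[TaggedRead], min_length: int
) -> tuple[list[TaggedRead], int]:
    """Keep reads whose trimmed sequence is at least ``min_length`` bases."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    reads = list(reads)
    kept = [r for r in reads if len(r.sequence) >= min_length]
    return kept, len(reads) - len(kept)


def dereplicate(reads: Iterable[TaggedRead]) -> list[Haplotype]:
    """Collapse identical sequences into haplotypes with abundances.

    Haplotypes are ordered by decreasing total abundance, ties broken
    by sequence, and given stable ids ``H000001``...
    """
    totals: Counter[str] = Counter()
    per_sample: dict[str, Counter[str]] = defaultdict(Counter)
    for read in reads:
        totals[read.sequence] += 1
        per_sample[read.sequence][read.assigned_sample or "unassigned"] += 1
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Haplotype(
            haplotype_id=f"H{i + 1:06d}",
            sequence=seq,
            total_abundance=count,
            per_sample_abundance=dict(per_sample[seq]),
        )
        for i, (seq, count) in enumerate(ordered)
    ]


def remove_singletons(
    haplotypes: Iterable[Haplotype], scope: str = "global"
) -> tuple[list[Haplotype], int]:
    """Drop haplotypes observed only once.

    ``scope="global"`` (default) removes haplotypes whose run-wide
    abundance is 1.  ``scope="per_sample"`` zeroes out single-read
    occurrences within each sample and drops haplotypes left with no
    occurrences at all — the stricter reading of singleton removal when
    applied after per-sample splitting.
    """
    if scope not in ("global", "per_sample"):
        raise ValueError(f"unknown singleton scope {scope!r}")
    kept: list[Haplotype] = []
    n_discarded_reads = 0
    for hap in haplotypes:
        if scope == "global":
            if hap.total_abundance == 1:
                n_discarded_reads += 1
            else:
                kept.append(hap)
        else:
            pruned = {s: c for s, c in hap.per_sample_abundance.items() if c > 1}
            removed = hap.total_abundance - sum(pruned.values())
            n_discarded_reads += removed
            if pruned:
                kept.append(
                    Haplotype(
                        hap.haplotype_id,
                        hap.sequence,
                        sum(pruned.values()),
                        pruned,
                    )
                )
    if not kept:
        logger.warning("singleton removal discarded every haplotype")
    return kept, n_discarded_reads


def run_filter_chain(
    reads: Sequence[TaggedRead],
    tag_map: Mapping[str, str],
    primer: str,
    min_length: int = 141,
    singleton_scope: str = "global",
) -> tuple[list[Haplotype], FilterReport]:
    """Run the full fixed-order filter chain and account for every read."""
    assigned, report = demultiplex(reads, tag_map, primer)
    long_enough, n_short = length_filter(assigned, min_length)
    haplotypes = dereplicate(long_enough)
    kept, n_singleton_reads = remove_singletons(haplotypes, scope=singleton_scope)
    report.discarded_short = n_short
    report.discarded_singletons = n_singleton_reads
    report.retained = sum(h.total_abundance for h in kept)
    report.validate()
    logger.info(
        "filter chain: %d in -> %d retained (%d primer, %d short, %d singleton reads removed)",
        report.input_reads,
        report.retained,
        report.discarded_primer_mismatch,
        report.discarded_short,
        report.discarded_singletons,
    )
    return kept, report


# ---------------------------------------------------------------------------
# file formats


def read_sequences(path: str | Path, fmt: str | None = None) -> list[TaggedRead]:
    """Read a FASTA or FASTQ file into :class:`TaggedRead` objects."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [TaggedRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_sequences(
    reads: Iterable[TaggedRead], path: str | Path, fmt: str | None = None, quality: int = 40
) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_tag_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (tag, sample_id) into a mapping."""
    tag_map: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tag, sample = line.split("\t")[:2]
        if tag in tag_map:
            raise ValueError(f"duplicate tag {tag!r} in tag map")
        tag_map[tag.upper()] = sample
    if not tag_map:
        raise ValueError(f"tag map {path} is empty")
    return tag_map


def write_tag_map(tag_map: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{tag}\t{sample}\n" for tag, sample in tag_map.items())
    )
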