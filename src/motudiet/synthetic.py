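"""Synthetic reference taxa, tagged amplicon reads, and diet matrices.

The generator emulates the inputs of a tagged-amplicon diet study so
the whole pipeline can be exercised with known ground truth:

* a reference panel of mock taxa whose base sequences are mutually
  divergent (> 4% by default) while intraspecific variants stay close
  (< 2% by default) — the separation regime under which a 2% clustering
  threshold recovers exactly one MOTU per taxon;
* tagged reads ``tag + primer + variant`` with per-base substitution
  errors and a truth table mapping every read to its source taxon;
* utilization matrices with a tunable overlap level between predator
  columns, for calibrating the niche-overlap null test.

Everything is driven by a single integer seed; identical seed and
configuration give identical output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import TaggedRead
from .diet import UtilizationMatrix

BASES = np.array(list("ACGT"))

#: concrete stand-in for a degenerate arthropod COI forward primer
DEFAULT_PRIMER = "AGATATTGGAACTTTATATTTTATTTTTGG"


class InfeasiblePanelError(RuntimeError):
    """Raised when the divergence constraints cannot be satisfied."""


@dataclass
class MockTaxon:
    """One synthetic reference taxon with intraspecific variants."""

    taxon_id: str
    lineage: tuple[str, str, str, str]  # (order, family, genus, species)
    base_sequence: str
    intraspecific_variants: list[str] = field(default_factory=list)

    @property
    def sequences(self) -> list[str]:
        """Base sequence first, then variants (haplotype rank order)."""
        return [self.base_sequence, *self.intraspecific_variants]


@dataclass
class ReadSimConfig:
    """Parameters of the read simulator."""

    n_samples_per_predator: int = 5
    tag_length: int = 8
    primer_forward: str = DEFAULT_PRIMER
    reads_per_sample: int = 100
    substitution_error_rate: float = 0.002
    abundance_skew: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must lie in [0, 1)")
        if min(self.n_samples_per_predator, self.tag_length, self.reads_per_sample) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.abundance_skew <= 1:
            raise ValueError("abundance_skew must lie in (0, 1]")


def _hamming_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, sequence: str, n_sub: int) -> str:
    """Apply exactly ``n_sub`` substitutions at distinct positions."""
    if n_sub == 0:
        return sequence
    seq = list(sequence)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def generate_reference_panel(
    n_taxa: int,
    length: int = 157,
    min_interspecific: float = 0.04,
    max_intraspecific: float = 0.02,
    seed: int = 0,
    n_variants: int = 2,
    max_tries: int = 1000,
) -> list[MockTaxon]:
    """Generate mock taxa satisfying the divergence constraints.

    Base sequences are drawn independently at random (rejection-sampled
    so every pair exceeds ``min_interspecific`` p-distance); variants
    carry strictly fewer substitutions than ``max_intraspecific`` of the
    sequence length.  Raises :class:`InfeasiblePanelError` rather than
    silently violating a constraint.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0 <= max_intraspecific < min_interspecific <= 1:
        raise ValueError("need 0 <= max_intraspecific < min_interspecific <= 1")
    rng = np.random.default_rng(seed)
    max_subs = int(np.floor(max_intraspecific * length - 1e-9))

    bases: list[str] = []
    for _ in range(n_taxa):
        for _attempt in range(max_tries):
            candidate = _random_sequence(rng, length)
            if all(
                _hamming_fraction(candidate, other) > min_interspecific
                for other in bases
            ):
                bases.append(candidate)
                break
        else:
            raise InfeasiblePanelError(
                f"could not place {n_taxa} taxa of length {length} with "
                f"pairwise divergence > {min_interspecific}"
            )

    panel = []
    for i, base in enumerate(bases):
        variants = []
        if max_subs >= 1:
            for _ in range(n_variants):
                n_sub = int(rng.integers(1, max_subs + 1))
                variants.append(_mutate(rng, base, n_sub))
        panel.append(
            MockTaxon(
                taxon_id=f"T{i + 1:03d}",
                lineage=(
                    f"Order{chr(65 + i % 5)}",
                    f"Family{i % 10:02d}",
                    f"Genus{i:02d}",
                    f"species_{i + 1:03d}",
                ),
                base_sequence=base,
                intraspecific_variants=variants,
            )
        )
    return panel


def generate_tags(
    n: int, length: int = 8, seed: int | np.random.Generator = 0, max_tries: int = 10_000
) -> list[str]:
    """Distinct fixed-length tags with pairwise Hamming distance >= 2."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tags: list[str] = []
    for _ in range(n):
        for _attempt in range(max_tries):
            cand = _random_sequence(rng, length)
            if all(sum(a != b for a, b in zip(cand, t)) >= 2 for t in tags):
                tags.append(cand)
                break
        else:
            raise InfeasiblePanelError(
                f"could not generate {n} tags of length {length} at Hamming >= 2"
            )
    return tags


def simulate_reads(
    panel: Sequence[MockTaxon],
    true_diet: Mapping[str, Mapping[str, int] | Sequence[str]],
    config: ReadSimConfig,
    tag_map: Mapping[str, str] | None = None,
) -> tuple[list[TaggedRead], pd.DataFrame, dict[str, str]]:
    """Simulate tagged amplicon reads from a planted diet.

    ``true_diet`` maps sample id to a taxon multiset (mapping taxon_id
    -> weight, or a sequence of taxon_ids with repetition).  Each read
    is ``tag + primer + variant-with-errors``; within a taxon the
    haplotype (base sequence, then variants) is drawn from a geometric
    series with ratio ``abundance_skew``.

    Returns the reads, a truth table (read_id, sample_id, taxon_id),
    and the tag-to-sample mapping used.
    """
    rng = np.random.default_rng(config.seed)
    taxa = {t.taxon_id: t for t in panel}
    for sample, diet in true_diet.items():
        for taxon_id in diet:
            if taxon_id not in taxa:
                raise ValueError(
                    f"sample {sample!r} lists taxon {taxon_id!r} not in the panel"
                )
    samples = list(true_diet)
    if tag_map is None:
        tags = generate_tags(len(samples), config.tag_length, rng)
        tag_map = dict(zip(tags, samples))
    else:
        if len(set(tag_map.values())) != len(tag_map):
            raise ValueError("each sample must have exactly one unique tag")
        missing = set(samples) - set(tag_map.values())
        if missing:
            raise ValueError(f"samples without a tag: {sorted(missing)}")
    sample_tag = {s: t for t, s in tag_map.items()}

    reads: list[TaggedRead] = []
    truth_rows = []
    for sample in samples:
        diet = true_diet[sample]
        if isinstance(diet, Mapping):
            taxon_ids = list(diet)
            weights = np.array([diet[t] for t in taxon_ids], dtype=float)
        else:
            counter = Counter(diet)
            taxon_ids = list(counter)
            weights = np.array([counter[t] for t in taxon_ids], dtype=float)
        weights = weights / weights.sum()
        tag = sample_tag[sample]
        for i in range(config.reads_per_sample):
            taxon = taxa[taxon_ids[rng.choice(len(taxon_ids), p=weights)]]
            variants = taxon.sequences
            w = config.abundance_skew ** np.arange(len(variants))
            w /= w.sum()
            template = variants[rng.choice(len(variants), p=w)]
            n_err = rng.binomial(len(template), config.substitution_error_rate)
            insert = _mutate(rng, template, int(n_err))
            read_id = f"{sample}_r{i:05d}"
            reads.append(
                TaggedRead(read_id, tag + config.primer_forward + insert)
            )
            truth_rows.append((read_id, sample, taxon.taxon_id))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample_id", "taxon_id"])
    return reads, truth, dict(tag_map)


def simulate_utilization_matrix(
    n_species: int,
    n_resources: int,
    overlap_level: float,
    seed: int = 0,
    total_per_species: int = 100,
) -> UtilizationMatrix:
    """Utilization matrix with a controlled interspecific overlap level.

    Each species' use profile is a mixture
    ``overlap_level * shared + (1 - overlap_level) * private``, where
    the shared profile is common to all species and the private
    profiles occupy disjoint resource blocks.  Proportions are
    converted to integer counts by largest-remainder rounding, so at
    ``overlap_level=1`` all rows are exactly identical and at
    ``overlap_level=0`` their supports are exactly disjoint.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0 <= overlap_level <= 1:
        raise ValueError("overlap_level must lie in [0, 1]")
    if n_resources < n_species:
        raise ValueError("need at least one resource per species")
    rng = np.random.default_rng(seed)

    shared = rng.dirichlet(np.ones(n_resources) * 2.0)
    blocks = np.array_split(np.arange(n_resources), n_species)
    columns = {}
    for s in range(n_species):
        private = np.zeros(n_resources)
        private[blocks[s]] = rng.dirichlet(np.ones(len(blocks[s])) * 2.0)
        p = overlap_level * shared + (1 - overlap_level) * private
        scaled = p * total_per_species
        counts = np.floor(scaled).astype(int)
        remainder = total_per_species - counts.sum()
        if remainder > 0:
            order = np.argsort(-(scaled - np.floor(scaled)), kind="stable")
            counts[order[:remainder]] += 1
        columns[f"S{s + 1:02d}"] = counts
    data = pd.DataFrame(
        columns, index=[f"R{r + 1:03d}" for r in range(n_resources)]
    )
    return UtilizationMatrix(data)


# ---------------------------------------------------------------------------
# file output


def write_reference_fasta(panel: Iterable[MockTaxon], path: str | Path) -> None:
    """Panel as FASTA, one record per sequence, headers
    ``>taxon_id|order|family|genus|species`` (variants suffixed)."""
    lines = []
    for taxon in panel:
        lineage = "|".join(taxon.lineage)
        for v, seq in enumerate(taxon.sequences):
            suffix = "" if v == 0 else f".v{v}"
            lines.append(f">{taxon.taxon_id}{suffix}|{lineage}")
            lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
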