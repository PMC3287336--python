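"""End-to-end pipeline orchestration.

Stages run in the fixed order of the analysis: demultiplex -> length
filter -> dereplicate -> singleton removal -> pairwise distances ->
threshold sweep -> MOTU clustering -> taxonomic assignment -> diet
statistics -> niche-overlap null test -> habitat contingency test.
Stages communicate through typed files (FASTA/TSV/JSON) under one run
directory, and a manifest records parameters, derived per-stage seeds,
and per-stage record counts, so a run can be audited and reproduced.

A single global seed is split deterministically into per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon import (
    read_sequences,
    read_tag_map,
    run_filter_chain,
)
from .clustering import (
    DistanceMatrix,
    cluster_at_threshold,
    select_infliction_threshold,
    sweep_thresholds,
    write_motu_table,
    write_representatives_fasta,
)
from .diet import UtilizationMatrix, build_matrix, niche_descriptors, sample_summary
from .fixtures import load_table1_fixture
from .habitat import HabitatTable, chi_square_independence, classify_diet
from .nullmodels import NicheOverlapModel
from .synthetic import DEFAULT_PRIMER
from .taxonomy import (
    assign_motu,
    read_checklist,
    read_reference_fasta,
    write_assignments_tsv,
)

logger = logging.getLogger(__name__)


def split_seed(seed: int, stage: int) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    return (seed * 1_000_003 + 7919 * stage + 1) % (2**31)


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    # input paths (None = stage skipped)
    reads: str | None = None
    tag_map: str | None = None
    sample_map: str | None = None  # TSV: sample_id <tab> predator
    reference: str | None = None
    checklist: str | None = None
    habitat_table: str | None = None
    use_table1_fixture: bool = False
    # filter parameters
    primer: str = DEFAULT_PRIMER
    min_length: int = 141
    singleton_scope: str = "global"
    # clustering parameters
    sweep_start: float = 0.0
    sweep_stop: float = 0.10
    sweep_step: float = 0.005
    plateau_tolerance: int = 0
    fixed_threshold: float | None = None
    # assignment thresholds
    species_threshold: float = 0.985
    family_threshold: float = 0.98
    # null model
    n_iterations: int = 10_000
    seed: int = 0
    # output
    outdir: str = "motudiet_run"

    def __post_init__(self) -> None:
        for name in ("species_threshold", "family_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("reads", "tag_map", "sample_map", "reference", "checklist",
                     "habitat_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _read_sample_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sample, predator = line.split("\t")[:2]
        mapping[sample] = predator
    if not mapping:
        raise ValueError(f"sample map {path} is empty")
    return mapping


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": {},
        "counts": {},
    }

    matrix: UtilizationMatrix | None = None
    presence: dict | None = None

    if config.use_table1_fixture:
        logger.info("fixture-only mode: skipping sequence stages")
        matrix = load_table1_fixture()
        matrix.to_tsv(outdir / "utilization_matrix.tsv")
        manifest["counts"]["resources"] = len(matrix.resources)
    else:
        if config.reads is None or config.tag_map is None:
            raise ValueError(
                "either reads+tag_map or use_table1_fixture must be configured"
            )
        try:
            reads = read_sequences(config.reads)
        except Exception as exc:  # noqa: BLE001 - stage name in the error
            raise RuntimeError(f"stage 'read input' failed: {exc}") from exc
        tag_map = read_tag_map(config.tag_map)
        haplotypes, report = run_filter_chain(
            reads,
            tag_map,
            config.primer,
            min_length=config.min_length,
            singleton_scope=config.singleton_scope,
        )
        report.to_json(outdir / "filter_report.json")
        manifest["counts"]["filter"] = report.__dict__
        manifest["counts"]["haplotypes"] = len(haplotypes)
        if not haplotypes:
            raise RuntimeError("stage 'filter' failed: no haplotypes retained")

        hap_index = {h.haplotype_id: h for h in haplotypes}
        dm = DistanceMatrix.from_haplotypes(haplotypes)
        sweep = sweep_thresholds(
            dm, config.sweep_start, config.sweep_stop, config.sweep_step
        )
        sweep.to_tsv(outdir / "threshold_sweep.tsv")
        if config.fixed_threshold is not None:
            threshold = config.fixed_threshold
            sweep.selected_threshold = threshold
        else:
            threshold = select_infliction_threshold(sweep, config.plateau_tolerance)
        manifest["selected_threshold"] = threshold

        clusters = cluster_at_threshold(dm, threshold, hap_index)
        write_motu_table(clusters, outdir / "motus.tsv")
        write_representatives_fasta(clusters, hap_index, outdir / "representatives.fasta")
        manifest["counts"]["motus"] = len(clusters)

        motu_names = {c.motu_id: c.motu_id for c in clusters}
        if config.reference is not None:
            checklist = (
                read_checklist(config.checklist) if config.checklist else None
            )
            reference = read_reference_fasta(config.reference, checklist)
            assignments = [
                assign_motu(
                    c.motu_id,
                    c.representatives,
                    reference,
                    config.species_threshold,
                    config.family_threshold,
                )
                for c in clusters
            ]
            write_assignments_tsv(assignments, outdir / "assignments.tsv")
            manifest["counts"]["assigned"] = sum(
                1 for a in assignments if a.assigned_rank != "unknown"
            )
            for a in assignments:
                if a.assigned_rank != "unknown":
                    motu_names[a.motu_id] = a.assigned_name

        # per-sample presence of MOTUs -> utilization matrix
        sample_map = (
            _read_sample_map(config.sample_map) if config.sample_map else None
        )
        presence = {}
        for c in clusters:
            label = motu_names[c.motu_id]
            for sample in c.per_sample_presence:
                predator = (
                    sample_map.get(sample, "all") if sample_map else "all"
                )
                presence.setdefault((sample, predator), set()).add(label)
        matrix = build_matrix(presence)
        matrix.to_tsv(outdir / "utilization_matrix.tsv")
        manifest["counts"]["resources"] = len(matrix.resources)

        per_sample = {s: res for (s, _p), res in presence.items()}
        summary = sample_summary(per_sample)
        manifest["sample_summary"] = {
            "mean": summary.mean,
            "sd": summary.sd,
            "min": summary.min,
            "max": summary.max,
        }

    # ---- statistics on the utilization matrix ---------------------------
    stats: dict = {"descriptors": {}}
    for predator in matrix.predators:
        col = matrix.column(predator)
        if col.sum() == 0:
            continue
        desc = niche_descriptors(col[col > 0])
        stats["descriptors"][predator] = vars(desc)
    if len(matrix.predators) >= 2:
        null_seed = split_seed(config.seed, 1)
        manifest["stage_seeds"]["null_model"] = null_seed
        model = NicheOverlapModel(matrix)
        results = model.fit(n_iterations=config.n_iterations, seed=null_seed)
        stats["niche_overlap"] = results.to_dict()
        (outdir / "overlap_summary.txt").write_text(results.summary() + "\n")
    (outdir / "diet_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    manifest["diet_stats"] = stats

    if config.habitat_table is not None and len(matrix.predators) >= 2:
        habitat = HabitatTable.from_tsv(config.habitat_table)
        try:
            table = classify_diet(matrix, habitat, specialists_only=True)
            chi = chi_square_independence(table)
            manifest["habitat_test"] = {
                "table": table.to_dict(),
                "chi_square": chi.statistic,
                "df": chi.df,
                "p_value": chi.p_value,
            }
            table.to_csv(outdir / "habitat_table.tsv", sep="\t")
        except ValueError as exc:
            manifest["habitat_test"] = {"error": str(exc)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete; outputs in %s", outdir)
    return manifest
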