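"""End-to-end driver: annotated genome + VCF (+ depth) -> category tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .filtering import (
    DEFAULT_THRESHOLDS,
    FilteredVariant,
    HardFilterThresholds,
    annotate_variants,
    read_vcf,
    tstv_summary,
)
from .genome import (
    AnnotatedGenome,
    CategoryPartition,
    assign_structural_regions,
    build_partition,
    category_lengths,
    cds_site_classes,
    load_annotation,
    load_genome,
    read_bed,
)
from .varstats import (
    compute_category_stats,
    neutrality_ratios,
    structural_stats,
    write_report,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    genome: AnnotatedGenome
    partition: CategoryPartition
    variants: list[FilteredVariant]  # annotated; includes failing records
    stats: pd.DataFrame
    structural: pd.DataFrame
    tstv: dict
    ratios: pd.DataFrame
    category_lengths: pd.DataFrame

    @property
    def passing(self) -> list[FilteredVariant]:
        return [v for v in self.variants if v.pass_filter]


def run_pipeline(
    fasta: str | Path,
    gff: str | Path,
    vcf: str | Path,
    repeats_bed: str | Path | None = None,
    ir_bed: str | Path | None = None,
    cds_mode: str = "site",
    site_mode: str = "fourfold",
    thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS,
    missing: str = "fail",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Partition the genome, hard-filter the variants, tabulate abundances."""
    genome = load_genome(fasta)
    load_annotation(gff, genome)
    classes, context = cds_site_classes(genome, mode=site_mode)
    repeats = read_bed(repeats_bed) if repeats_bed else None
    partition = build_partition(genome, site_classes=classes,
                                repeats=repeats, cds_context=context)
    if ir_bed:
        irs = read_bed(ir_bed)
        if len(irs) != 2:
            raise ValueError(f"IR BED must contain exactly 2 intervals, "
                             f"got {len(irs)}")
        assign_structural_regions(partition, irs[0], irs[1], genome=genome)

    raw, _samples = read_vcf(vcf)
    variants = annotate_variants(raw, thresholds, missing=missing)
    passing = [v for v in variants if v.pass_filter]
    stats = compute_category_stats(passing, partition, cds_mode=cds_mode)
    structural = structural_stats(passing, partition, cds_mode=cds_mode) \
        if ir_bed else pd.DataFrame()
    tstv = tstv_summary(passing)
    ratios = neutrality_ratios(stats)
    result = PipelineResult(
        genome=genome, partition=partition, variants=variants, stats=stats,
        structural=structural, tstv=tstv, ratios=ratios,
        category_lengths=category_lengths(partition),
    )
    if out_dir:
        write_report(stats, tstv, out_dir,
                     structural=structural if not structural.empty else None)
        ratios.to_csv(Path(out_dir) / "neutrality_ratios.tsv", sep="\t",
                      index=False, na_rep="NA")
    return result
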