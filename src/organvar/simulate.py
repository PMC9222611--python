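"""Synthetic annotated organelle genomes, population VCFs and depth tables.

The generator emulates the inputs of the whole pipeline so every stage runs
without any download: a circular genome with valid ORFs, introns, rRNA/tRNA
genes, a pseudogene, exact duplicated repeats and (optionally) an inverted
repeat pair; a multi-sample haploid VCF in which each functional category
mutates at its own per-site rate and the GATK-style QUAL/QD/FS/MQ fields
fail the hard filter at a configured fraction; and per-site depth tables
with implanted copy-number segments.

Rate semantics: ``snp_rates[c]`` is the expected per-site rate of
HIGH-CONFIDENCE (filter-passing) SNPs in category ``c``.  The raw per-site
event rate is inflated by 1/(1 - f_fail) so that an expected fraction
``f_fail`` of emitted records fails the hard filter while the post-filter
abundance still estimates ``snp_rates[c]`` — this is the quantity the
pipeline's parameter-recovery checks target.

Default magnitudes follow the published per-category abundances of a
gymnosperm mitogenome (about 0.0006–0.0012 SNPs per site, ts:tv near 2),
with a 200-kb genome, 40 sampled accessions, 50x depth and one 2-fold
15-kb CNV segment over three depth replicates.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .degeneracy import STANDARD_CODE
from .filtering import RawVariant, write_vcf
from .genome import (
    AnnotatedGenome,
    CategoryPartition,
    Feature,
    Functional,
    Interval,
    _revcomp,
    build_partition,
)

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_SENSE = sorted(c for c, aa in STANDARD_CODE.codon_to_aa.items() if aa != "*")
_STOPS = sorted(c for c, aa in STANDARD_CODE.codon_to_aa.items() if aa == "*")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class FeaturePlan:
    """Counts and length ranges (bp) for the generated feature set."""

    n_cds: int = 12
    cds_length: tuple[int, int] = (900, 2400)
    introns_per_cds: tuple[int, int] = (0, 2)
    intron_length: tuple[int, int] = (600, 1500)
    n_rrna: int = 3
    rrna_length: tuple[int, int] = (1200, 2900)
    n_trna: int = 15
    trna_length: tuple[int, int] = (70, 90)
    n_pseudogene: int = 1
    pseudogene_length: tuple[int, int] = (800, 1600)
    n_repeat_pairs: int = 3
    repeat_length: tuple[int, int] = (2000, 6000)
    ir_length: int = 0  # > 0 generates a plastid-style inverted repeat pair


@dataclass
class DepthPlan:
    mean_depth: float = 50.0
    noise: str = "poisson"  # "poisson" | "none"
    cnv_segments: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(120_000, 135_000, 2.0)])
    n_samples: int = 3


def _default_snp_rates() -> dict[str, float]:
    return {
        "NONSYN_SITE": 0.0008,
        "SYN_SITE": 0.0009,
        "RRNA": 0.0012,
        "TRNA": 0.0011,
        "PSEUDOGENE": 0.0009,
        "INTRON": 0.0006,
        "INTERGENIC": 0.0009,
    }


def _default_indel_rates() -> dict[str, float]:
    return {
        "NONSYN_SITE": 0.0,
        "SYN_SITE": 0.0,
        "RRNA": 0.0002,
        "TRNA": 0.0,
        "PSEUDOGENE": 0.0,
        "INTRON": 0.0003,
        "INTERGENIC": 0.0005,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 200_000
    seq_id: str = "sim_mito"
    features: FeaturePlan = field(default_factory=FeaturePlan)
    n_samples: int = 40
    snp_rates: dict[str, float] = field(default_factory=_default_snp_rates)
    indel_rates: dict[str, float] = field(default_factory=_default_indel_rates)
    ts_tv_bias: float = 2.0
    f_fail: float = 0.3
    multiallelic_fraction: float = 0.0
    depth: DepthPlan = field(default_factory=DepthPlan)

    def __post_init__(self) -> None:
        for rates in (self.snp_rates, self.indel_rates):
            for key, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate {key}={p} outside [0, 1]")
        if not 0.0 <= self.f_fail < 1.0:
            raise ValueError("f_fail must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "features" in raw:
            raw["features"] = FeaturePlan(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["features"].items()})
        if "depth" in raw:
            depth = dict(raw["depth"])
            if "cnv_segments" in depth:
                depth["cnv_segments"] = [tuple(seg)
                                         for seg in depth["cnv_segments"]]
            raw["depth"] = DepthPlan(**depth)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = [_SENSE[i] for i in rng.integers(0, len(_SENSE), size=n_codons - 2)]
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(body) + stop


@dataclass
class _Block:
    seq: str
    features: list[Feature]  # coordinates relative to block start
    repeat_pair: int | None = None
    ir: str | None = None  # "IRA" | "IRB"


def _cds_gene_block(rng: np.random.Generator, plan: FeaturePlan,
                    gene_id: str) -> _Block:
    lo, hi = plan.cds_length
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    orf = _random_orf(rng, n_codons)
    k = int(rng.integers(plan.introns_per_cds[0], plan.introns_per_cds[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    # split the ORF into k+1 exons at random interior boundaries
    if k:
        cuts = np.sort(rng.choice(np.arange(3, len(orf) - 3), size=k,
                                  replace=False))
        exons = [orf[a:b] for a, b in
                 zip(np.concatenate(([0], cuts)),
                     np.concatenate((cuts, [len(orf)])))]
        introns = [_random_seq(rng, int(rng.integers(*plan.intron_length)))
                   for _ in range(k)]
    else:
        exons, introns = [orf], []
    pre = exons[0]
    exon_offsets = [(0, len(exons[0]))]
    for intron, exon in zip(introns, exons[1:]):
        pre += intron
        exon_offsets.append((len(pre), len(pre) + len(exon)))
        pre += exon
    if strand == "+":
        block_seq = pre
        parts = exon_offsets
    else:
        block_seq = _revcomp(pre)
        n = len(pre)
        parts = sorted((n - e, n - s) for s, e in exon_offsets)
    # transcription order: ascending for +, descending for -
    tx_parts = parts if strand == "+" else parts[::-1]
    phases = []
    cum = 0
    for s, e in tx_parts:
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    feats = [
        Feature(kind="gene", strand=strand, parts=[(0, len(block_seq))],
                id=gene_id),
        Feature(kind="CDS", strand=strand, parts=list(tx_parts), id=f"cds:{gene_id}",
                parent=gene_id, phases=phases),
    ]
    return _Block(seq=block_seq, features=feats)


def _simple_gene_block(rng: np.random.Generator, kind: str, length: int,
                       gene_id: str) -> _Block:
    seq = _random_seq(rng, length)
    strand = "+" if rng.random() < 0.5 else "-"
    feats = [Feature(kind="gene", strand=strand, parts=[(0, length)], id=gene_id),
             Feature(kind=kind, strand=strand, parts=[(0, length)],
                     id=f"{kind}:{gene_id}", parent=gene_id)]
    return _Block(seq=seq, features=feats)


def generate_genome(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotatedGenome, list[Interval], tuple[Interval, Interval] | None]:
    """Random annotated circular genome per the feature plan.

    Returns the genome, the repeat intervals (both copies of each exact
    duplication) and the IR interval pair (or None).  Raises before any
    output when the plan does not fit in the genome.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    plan = cfg.features
    blocks: list[_Block] = []
    for i in range(plan.n_cds):
        blocks.append(_cds_gene_block(rng, plan, f"gene{i + 1}"))
    for i in range(plan.n_rrna):
        blocks.append(_simple_gene_block(
            rng, "rRNA", int(rng.integers(*plan.rrna_length)), f"rrn{i + 1}"))
    for i in range(plan.n_trna):
        blocks.append(_simple_gene_block(
            rng, "tRNA", int(rng.integers(*plan.trna_length)), f"trn{i + 1}"))
    for i in range(plan.n_pseudogene):
        length = int(rng.integers(*plan.pseudogene_length))
        blocks.append(_Block(
            seq=_random_seq(rng, length),
            features=[Feature(kind="pseudogene", strand="+",
                              parts=[(0, length)], id=f"pseudo{i + 1}")]))
    for i in range(plan.n_repeat_pairs):
        length = int(rng.integers(*plan.repeat_length))
        seq = _random_seq(rng, length)
        blocks.append(_Block(seq=seq, features=[], repeat_pair=i))
        blocks.append(_Block(seq=seq, features=[], repeat_pair=i))
    if plan.ir_length > 0:
        seq = _random_seq(rng, plan.ir_length)
        blocks.append(_Block(seq=seq, features=[], ir="IRA"))
        blocks.append(_Block(seq=_revcomp(seq), features=[], ir="IRB"))

    total = sum(len(b.seq) for b in blocks)
    spare = cfg.genome_length - total
    if spare < len(blocks) + 1:
        raise ValueError(
            f"feature plan needs {total} bp plus gaps but genome is only "
            f"{cfg.genome_length} bp")
    rng.shuffle(blocks)
    gaps = rng.multinomial(spare, np.full(len(blocks) + 1,
                                          1.0 / (len(blocks) + 1)))
    pieces: list[str] = []
    features: list[Feature] = []
    repeat_pairs: dict[int, list[Interval]] = {}
    irs: dict[str, Interval] = {}
    cursor = 0
    for gap, block in zip(gaps, blocks):
        cursor += int(gap)
        pieces.append(_random_seq(rng, int(gap)))
        start = cursor
        for f in block.features:
            features.append(Feature(
                kind=f.kind, strand=f.strand,
                parts=[(s + start, e + start) for s, e in f.parts],
                id=f.id, parent=f.parent, phases=f.phases))
        if block.repeat_pair is not None:
            repeat_pairs.setdefault(block.repeat_pair, []).append(
                (start, start + len(block.seq)))
        if block.ir:
            irs[block.ir] = (start, start + len(block.seq))
        pieces.append(block.seq)
        cursor += len(block.seq)
    pieces.append(_random_seq(rng, int(gaps[-1])))
    # both copies of each exact duplication, pair-adjacent
    repeats = [iv for pid in sorted(repeat_pairs) for iv in repeat_pairs[pid]]
    sequence = "".join(pieces)
    assert len(sequence) == cfg.genome_length
    genome = AnnotatedGenome(seq_id=cfg.seq_id, sequence=sequence,
                             circular=True, features=features)
    genome.validate()
    ir_pair = (irs["IRA"], irs["IRB"]) if irs else None
    return genome, repeats, ir_pair


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_gff(genome: AnnotatedGenome, path: str | Path) -> None:
    """GFF3 export (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.seq_id} 1 {genome.length}\n")
        for f in genome.features:
            gff_type = {"repeat": "repeat_region", "IR": "inverted_repeat"
                        }.get(f.kind, f.kind)
            for i, (s, e) in enumerate(f.parts):
                attrs = []
                fid = f.id if len(f.parts) == 1 else f"{f.id}.{i + 1}"
                attrs.append(f"ID={fid}")
                if f.parent:
                    attrs.append(f"Parent={f.parent}")
                phase = (str(f.phases[i]) if f.kind == "CDS" and f.phases
                         else ".")
                fh.write("\t".join((
                    genome.seq_id, "organvar-sim", gff_type, str(s + 1),
                    str(e), ".", f.strand, phase, ";".join(attrs))) + "\n")


def write_bed(intervals: list[Interval], seq_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{seq_id}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Variant simulation


def _draw_info(rng: np.random.Generator, fail: bool) -> tuple[float, float, float, float]:
    """QUAL/QD/FS/MQ; when ``fail``, exactly one field is drawn failing."""
    qual = float(rng.uniform(60.0, 2000.0))
    qd = float(rng.uniform(20.0, 40.0))
    fs = float(rng.uniform(0.0, 10.0))
    mq = float(rng.uniform(30.0, 60.0))
    if fail:
        which = int(rng.integers(0, 4))
        if which == 0:
            qual = float(rng.uniform(0.0, 59.9))
        elif which == 1:
            qd = float(rng.uniform(0.0, 19.9))
        elif which == 2:
            fs = float(rng.uniform(10.1, 60.0))
        else:
            mq = float(rng.uniform(0.0, 29.9))
    return qual, qd, fs, mq


def _snp_alt(rng: np.random.Generator, ref: str, bias: float) -> str:
    if rng.random() < bias / (bias + 1.0):
        return _TRANSITION[ref]
    choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return choices[int(rng.integers(0, 2))]


def simulate_variants(
    genome: AnnotatedGenome,
    partition: CategoryPartition,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[RawVariant]:
    """Multi-sample variant records with category-specific per-site rates.

    Each position becomes a SNP (or indel) site independently with the raw
    rate mu_c/(1 - f_fail) of its functional category; the minor allele
    count is uniform on 1..n_samples//2; QUAL/QD/FS/MQ are drawn so that a
    fraction f_fail of records fails the hard filter.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    L = genome.length
    inflate = 1.0 / (1.0 - cfg.f_fail)
    mu_snp = np.zeros(L)
    mu_indel = np.zeros(L)
    for name, rate in cfg.snp_rates.items():
        mu_snp[partition.functional == Functional[name]] = rate * inflate
    for name, rate in cfg.indel_rates.items():
        mu_indel[partition.functional == Functional[name]] = rate * inflate
    draw = rng.random(L)
    snp_pos = np.flatnonzero(draw < mu_snp)
    indel_pos = np.flatnonzero((draw >= mu_snp)
                               & (rng.random(L) < mu_indel))
    n = cfg.n_samples
    variants: list[RawVariant] = []
    is_snp_site = np.zeros(L, dtype=bool)
    is_snp_site[snp_pos] = True
    for pos0 in sorted(np.concatenate((snp_pos, indel_pos)).tolist()):
        ref_base = genome.sequence[pos0]
        if ref_base not in "ACGT":
            continue
        if is_snp_site[pos0]:
            alts = [_snp_alt(rng, ref_base, cfg.ts_tv_bias)]
            if cfg.multiallelic_fraction and rng.random() < cfg.multiallelic_fraction:
                extra = [b for b in "ACGT" if b not in (ref_base, alts[0])]
                alts.append(extra[int(rng.integers(0, len(extra)))])
            ref = ref_base
        else:
            if rng.random() < 0.5 and pos0 + 5 < L:  # deletion
                dlen = int(rng.integers(1, 5))
                ref = genome.sequence[pos0:pos0 + dlen + 1]
                alts = [ref_base]
            else:  # insertion
                alts = [ref_base + _random_seq(rng, int(rng.integers(1, 5)))]
                ref = ref_base
        minor = int(rng.integers(1, max(n // 2, 1) + 1))
        genotypes: list[int | None] = [0] * n
        carriers = rng.choice(n, size=minor, replace=False)
        for j, sample in enumerate(carriers):
            genotypes[sample] = 1 + (j % len(alts))
        qual, qd, fs, mq = _draw_info(rng, rng.random() < cfg.f_fail)
        variants.append(RawVariant(
            seq_id=genome.seq_id, pos=pos0 + 1, ref=ref, alts=tuple(alts),
            qual=qual, qd=qd, fs=fs, mq=mq, genotypes=genotypes))
    return variants


# ---------------------------------------------------------------------------
# Depth simulation


def simulate_depth(
    genome_length: int,
    plan: DepthPlan,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-site depths: noise around mean*k inside CNV segments, mean outside."""
    rng = rng or np.random.default_rng(0)
    lam = np.full(genome_length, plan.mean_depth, dtype=np.float64)
    covered = np.zeros(genome_length, dtype=bool)
    for s, e, k in plan.cnv_segments:
        if not (0 <= s < e <= genome_length):
            raise ValueError(f"CNV segment ({s}, {e}) outside genome")
        if covered[s:e].any():
            raise ValueError("CNV segments overlap")
        covered[s:e] = True
        lam[s:e] *= k
    if plan.noise == "poisson":
        return rng.poisson(lam).astype(np.int64)
    if plan.noise == "none":
        return np.round(lam).astype(np.int64)
    raise ValueError(f"unknown noise law {plan.noise!r}")


def write_depth_tsv(depths: np.ndarray, seq_id: str, path: str | Path) -> None:
    """samtools-depth style TSV; zero-coverage positions are omitted."""
    nz = np.flatnonzero(depths > 0)
    with open(path, "w") as fh:
        for pos0 in nz:
            fh.write(f"{seq_id}\t{pos0 + 1}\t{depths[pos0]}\n")


# ---------------------------------------------------------------------------
# End-to-end fixture


def end_to_end_fixture(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """One call producing a complete runnable input set plus ground truth.

    Writes genome.fasta, annotation.gff3, repeats.bed, (ir.bed,)
    variants.vcf, depth_sample<i>.tsv and truth.json under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, repeats, ir_pair = generate_genome(cfg, rng)
    partition = build_partition(genome, repeats=repeats)
    variants = simulate_variants(genome, partition, cfg, rng)

    paths = {
        "fasta": out_dir / "genome.fasta",
        "gff": out_dir / "annotation.gff3",
        "repeats_bed": out_dir / "repeats.bed",
        "vcf": out_dir / "variants.vcf",
        "truth": out_dir / "truth.json",
    }
    write_fasta(genome, paths["fasta"])
    write_gff(genome, paths["gff"])
    write_bed(repeats, genome.seq_id, paths["repeats_bed"])
    if ir_pair is not None:
        paths["ir_bed"] = out_dir / "ir.bed"
        write_bed(list(ir_pair), genome.seq_id, paths["ir_bed"])
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    write_vcf(variants, samples, genome.seq_id, genome.length, paths["vcf"])

    depth_paths = []
    for i in range(cfg.depth.n_samples):
        depths = simulate_depth(genome.length, cfg.depth, rng)
        p = out_dir / f"depth_sample{i + 1}.tsv"
        write_depth_tsv(depths, genome.seq_id, p)
        depth_paths.append(p)
    paths["depth"] = depth_paths

    sites = {f.name: int(np.count_nonzero(partition.functional == f))
             for f in Functional}
    truth = {
        "seed": cfg.seed,
        "genome_length": genome.length,
        "n_samples": cfg.n_samples,
        "snp_rates": cfg.snp_rates,
        "indel_rates": cfg.indel_rates,
        "ts_tv_bias": cfg.ts_tv_bias,
        "f_fail": cfg.f_fail,
        "category_sites": sites,
        "repeats": [list(iv) for iv in repeats],
        "ir": [list(iv) for iv in ir_pair] if ir_pair else None,
        "mean_depth": cfg.depth.mean_depth,
        "cnv_segments": [list(seg) for seg in cfg.depth.cnv_segments],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["genome"] = genome
    paths["partition"] = partition
    paths["truth_dict"] = truth
    return paths
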