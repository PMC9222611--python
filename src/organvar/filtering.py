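"""Hard filtering and summary statistics for organelle population variants.

Variant calls arrive as VCF with GATK-style site annotations.  A site is
kept only when QUAL >= 60, QD >= 20.0, FS <= 10.0 and MQ >= 30.0 (i.e. it
fails on QUAL < 60, QD < 20.0, FS > 10.0 or MQ < 30.0; the inequalities are
strict).  Genotypes carry haploid semantics: organelle genomes are
effectively haploid, so diploid-encoded homozygous calls collapse to a
single allele and heteroplasmic-style heterozygous calls collapse to the
most frequent allele of the call (ties to the lower allele index, logged).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

TRANSITION = "TRANSITION"
TRANSVERSION = "TRANSVERSION"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class HardFilterThresholds:
    qual: float = 60.0
    qd: float = 20.0
    fs: float = 10.0
    mq: float = 30.0


DEFAULT_THRESHOLDS = HardFilterThresholds()


@dataclass
class RawVariant:
    seq_id: str
    pos: int  # 1-based reference position
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    genotypes: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError(f"empty REF at {self.seq_id}:{self.pos}")
        if not self.alts:
            raise ValueError(f"no ALT allele at {self.seq_id}:{self.pos}")


@dataclass
class FilteredVariant(RawVariant):
    var_type: str = "SNP"  # SNP | INDEL
    biallelic: bool = True
    subst_type: str = "NA"  # TRANSITION | TRANSVERSION | NA
    maf: float | None = None
    pass_filter: bool = True
    filter_reasons: list[str] = field(default_factory=list)


def _collapse_genotype(gt: tuple[int | None, ...]) -> int | None:
    """Collapse a (possibly diploid) GT tuple to one haploid allele index."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    counts = Counter(alleles)
    if len(counts) > 1:
        log.debug("heterozygous call %s collapsed to major allele", gt)
    top = max(counts.values())
    return min(a for a, c in counts.items() if c == top)


def read_vcf(path: str | Path) -> tuple[list[RawVariant], list[str]]:
    """Read a (plain-text or bgzipped) VCF into RawVariant records."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[RawVariant] = []
    for rec in vf:
        if rec.alts is None:
            continue

        def _info(key: str) -> float | None:
            val = rec.info.get(key)
            if val is None:
                return None
            if isinstance(val, (tuple, list)):
                val = val[0]
            return float(val)

        genotypes = [_collapse_genotype(rec.samples[s].get("GT", (None,)))
                     for s in samples]
        variants.append(RawVariant(
            seq_id=rec.chrom, pos=rec.pos, ref=rec.ref,
            alts=tuple(a for a in rec.alts if a is not None),
            qual=rec.qual, qd=_info("QD"), fs=_info("FS"), mq=_info("MQ"),
            genotypes=genotypes,
        ))
    vf.close()
    return variants, samples


def hard_filter(
    v: RawVariant,
    thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS,
    missing: str = "fail",
) -> tuple[bool, list[str]]:
    """Pure pass/fail predicate with the failing reasons.

    A variant fails on QUAL < qual, QD < qd, FS > fs or MQ < mq (strict
    inequalities).  Missing annotation fields fail by default (``missing=
    'fail'``) or are ignored (``missing='pass'``).
    """
    reasons: list[str] = []
    checks = (
        ("QUAL", v.qual, lambda x: x < thresholds.qual, f"QUAL<{thresholds.qual:g}"),
        ("QD", v.qd, lambda x: x < thresholds.qd, f"QD<{thresholds.qd:g}"),
        ("FS", v.fs, lambda x: x > thresholds.fs, f"FS>{thresholds.fs:g}"),
        ("MQ", v.mq, lambda x: x < thresholds.mq, f"MQ<{thresholds.mq:g}"),
    )
    for name, value, fails, tag in checks:
        if value is None:
            if missing == "fail":
                log.debug("missing %s at %s:%d -> fail", name, v.seq_id, v.pos)
                reasons.append(f"missing:{name}")
            continue
        if fails(value):
            reasons.append(tag)
    return (not reasons), reasons


def classify_substitution(ref: str, alt: str) -> str:
    """A<->G and C<->T are transitions; everything else is a transversion."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not single bases: {ref!r} -> {alt!r}")
    if ref == alt:
        raise ValueError(f"identical bases {ref!r}; not a substitution")
    same_class = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


def minor_allele_frequency(genotypes: Sequence[int | None]) -> float:
    """MAF over non-missing sampled accessions (reference is not a sample).

    The MAF is the second-largest allele frequency; a site monomorphic in
    the sample (including sites fixed for a non-reference allele) has
    MAF 0.
    """
    observed = [g for g in genotypes if g is not None]
    if not observed:
        raise ValueError("all genotypes missing; MAF undefined")
    counts = np.bincount(observed)
    freqs = np.sort(counts / len(observed))[::-1]
    return float(freqs[1]) if freqs.size > 1 else 0.0


def annotate_variants(
    variants: Iterable[RawVariant],
    thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS,
    missing: str = "fail",
) -> list[FilteredVariant]:
    """Type, Ts/Tv class, MAF and filter status for each raw variant.

    Sites with no called genotype are skipped with a warning.
    """
    out: list[FilteredVariant] = []
    for v in variants:
        passed, reasons = hard_filter(v, thresholds, missing)
        is_snp = len(v.ref) == 1 and all(len(a) == 1 for a in v.alts)
        biallelic = len(v.alts) == 1
        subst = "NA"
        if is_snp and biallelic:
            subst = classify_substitution(v.ref, v.alts[0])
        try:
            maf = minor_allele_frequency(v.genotypes) if v.genotypes else None
        except ValueError:
            log.warning("all genotypes missing at %s:%d; site skipped",
                        v.seq_id, v.pos)
            continue
        out.append(FilteredVariant(
            seq_id=v.seq_id, pos=v.pos, ref=v.ref, alts=v.alts, qual=v.qual,
            qd=v.qd, fs=v.fs, mq=v.mq, genotypes=v.genotypes,
            var_type="SNP" if is_snp else "INDEL", biallelic=biallelic,
            subst_type=subst, maf=maf, pass_filter=passed,
            filter_reasons=reasons,
        ))
    return out


def merge_accessions(
    variant_sets: Sequence[Sequence[RawVariant]],
    sample_names: Sequence[str],
    absent: str = "ref",
) -> list[RawVariant]:
    """Union of per-accession call sets into one site x sample table.

    Accessions without a record at a merged site hold the reference allele
    (``absent='ref'``) or a missing genotype (``absent='missing'``).  Alleles
    are deduplicated with first-seen alt order.  A conflicting REF at the
    same position is an error.
    """
    if len(variant_sets) != len(sample_names):
        raise ValueError("one sample name per accession call set required")
    sites: dict[tuple[str, int], dict] = {}
    for acc_idx, variants in enumerate(variant_sets):
        for v in variants:
            key = (v.seq_id, v.pos)
            site = sites.get(key)
            if site is None:
                site = sites[key] = {
                    "ref": v.ref, "alts": [], "gts": {}, "quals": [],
                    "qds": [], "fss": [], "mqs": [],
                }
            elif site["ref"] != v.ref:
                raise ValueError(
                    f"conflicting REF at {v.seq_id}:{v.pos}: "
                    f"{site['ref']!r} vs {v.ref!r}")
            gt = v.genotypes[0] if v.genotypes else 1
            if gt is None:
                merged_gt: int | None = None
            elif gt == 0:
                merged_gt = 0
            else:
                allele = v.alts[gt - 1]
                if allele not in site["alts"]:
                    site["alts"].append(allele)
                merged_gt = site["alts"].index(allele) + 1
            site["gts"][acc_idx] = merged_gt
            for store, val in (("quals", v.qual), ("qds", v.qd),
                               ("fss", v.fs), ("mqs", v.mq)):
                if val is not None:
                    site[store].append(val)
    default_gt = 0 if absent == "ref" else None
    merged: list[RawVariant] = []
    for (seq_id, pos) in sorted(sites, key=lambda k: (k[0], k[1])):
        site = sites[(seq_id, pos)]
        if not site["alts"]:  # every record was reference-only
            continue
        genotypes = [site["gts"].get(i, default_gt)
                     for i in range(len(sample_names))]
        merged.append(RawVariant(
            seq_id=seq_id, pos=pos, ref=site["ref"], alts=tuple(site["alts"]),
            qual=min(site["quals"]) if site["quals"] else None,
            qd=min(site["qds"]) if site["qds"] else None,
            fs=max(site["fss"]) if site["fss"] else None,
            mq=min(site["mqs"]) if site["mqs"] else None,
            genotypes=genotypes,
        ))
    return merged


def tstv_summary(variants: Iterable[FilteredVariant]) -> dict:
    """Transition/transversion summary over biallelic SNPs only.

    Multi-allelic SNPs are excluded.  The ratio is None (reported NA) when
    there are no transversions.
    """
    ts = tv = 0
    for v in variants:
        if v.var_type != "SNP" or not v.biallelic:
            continue
        if v.subst_type == TRANSITION:
            ts += 1
        elif v.subst_type == TRANSVERSION:
            tv += 1
    ratio = (ts / tv) if tv else None
    return {"n_biallelic": ts + tv, "transitions": ts, "transversions": tv,
            "ratio": ratio}


def write_site_table(variants: Iterable[FilteredVariant], path: str | Path) -> None:
    rows = [{
        "seq_id": v.seq_id, "pos": v.pos, "ref": v.ref,
        "alts": ",".join(v.alts), "type": v.var_type,
        "subst_type": v.subst_type,
        "maf": round(v.maf, 4) if v.maf is not None else "NA",
        "pass": v.pass_filter,
        "filter_reasons": ";".join(v.filter_reasons) or ".",
    } for v in variants]
    pd.DataFrame(rows, columns=["seq_id", "pos", "ref", "alts", "type",
                                "subst_type", "maf", "pass", "filter_reasons"]
                 ).to_csv(path, sep="\t", index=False)


def write_vcf(
    variants: Sequence[RawVariant],
    samples: Sequence[str],
    contig: str,
    contig_length: int,
    path: str | Path,
) -> None:
    """Write variants as an uncompressed multi-sample VCF with haploid GTs."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,'
                    'Description="Quality by depth">')
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,'
                    'Description="Fisher strand bias (phred)">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,'
                    'Description="RMS mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for v in sorted(variants, key=lambda x: (x.seq_id, x.pos)):
        rec = out.new_record(contig=v.seq_id, start=v.pos - 1,
                             alleles=(v.ref, *v.alts), qual=v.qual)
        if v.qd is not None:
            rec.info["QD"] = v.qd
        if v.fs is not None:
            rec.info["FS"] = v.fs
        if v.mq is not None:
            rec.info["MQ"] = v.mq
        for s, g in zip(samples, v.genotypes):
            rec.samples[s]["GT"] = (g,)
        out.write(rec)
    out.close()
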