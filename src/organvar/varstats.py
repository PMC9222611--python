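"""Per-category variant abundance tables and neutrality ratios.

Filtered variants are assigned to the three partition layers at their
(anchor) position and tabulated per functional category, per copy layer
(single-copy vs repeat) and — for plastids — per structural region
(LSC / SSC / IR, the two inverted repeats merged into one IR stratum).
Abundance is the per-site rate count/sites of each category; the MAF
column is the arithmetic mean minor allele frequency of the category's
variants.  Neutrality ratios compare each functional category's SNP
abundance with the intergenic baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .degeneracy import GeneticCode, STANDARD_CODE
from .filtering import FilteredVariant, tstv_summary
from .genome import CategoryPartition, CopyLayer, Functional, Structural, _revcomp

log = logging.getLogger(__name__)

#: report row order, mirroring the published table layout
ROW_ORDER = ("Protein Coding", "Nonsynonymous", "Synonymous", "rRNA", "tRNA",
             "Pseudogene", "Intron", "Intergenic", "Single-copy region",
             "Repeat", "Total")

_FUNC_ROW = {
    Functional.NONSYN_SITE: "Nonsynonymous",
    Functional.SYN_SITE: "Synonymous",
    Functional.RRNA: "rRNA",
    Functional.TRNA: "tRNA",
    Functional.PSEUDOGENE: "Pseudogene",
    Functional.INTRON: "Intron",
    Functional.INTERGENIC: "Intergenic",
}

STATS_COLUMNS = ("sequence_type", "sites", "snps", "snps_per_site", "snp_maf",
                 "indels", "indels_per_site", "indel_maf")


def assign_category(
    v: FilteredVariant,
    partition: CategoryPartition,
    cds_mode: str = "site",
    code: GeneticCode = STANDARD_CODE,
) -> tuple[Functional, CopyLayer, Structural]:
    """Labels per layer for one variant (anchored at its VCF POS).

    With ``cds_mode='site'`` a CDS SNP inherits the degeneracy-derived site
    class of its position; with ``cds_mode='effect'`` a biallelic CDS SNP is
    synonymous iff the alternate codon translates identically.
    """
    pos0 = v.pos - 1
    if not 0 <= pos0 < partition.length:
        raise ValueError(f"position {v.pos} outside genome of length "
                         f"{partition.length}")
    func = Functional(partition.functional[pos0])
    if (cds_mode == "effect"
            and func in (Functional.NONSYN_SITE, Functional.SYN_SITE)
            and v.var_type == "SNP" and v.biallelic
            and pos0 in partition.cds_context):
        codon, offset, strand = partition.cds_context[pos0]
        alt = v.alts[0] if strand == "+" else _revcomp(v.alts[0])
        mutant = codon[:offset] + alt + codon[offset + 1:]
        same = code.codon_to_aa.get(mutant) == code.codon_to_aa.get(codon)
        func = Functional.SYN_SITE if same else Functional.NONSYN_SITE
    return (func, CopyLayer(partition.copy_layer[pos0]),
            Structural(partition.structural[pos0]))


@dataclass
class _Acc:
    snps: int = 0
    indels: int = 0
    snp_mafs: list[float] | None = None
    indel_mafs: list[float] | None = None

    def __post_init__(self) -> None:
        self.snp_mafs = []
        self.indel_mafs = []

    def add(self, v: FilteredVariant) -> None:
        if v.var_type == "SNP":
            self.snps += 1
            if v.maf is not None:
                self.snp_mafs.append(v.maf)
        else:
            self.indels += 1
            if v.maf is not None:
                self.indel_mafs.append(v.maf)


def _row(name: str, sites: int, acc: _Acc, maf_agg: str) -> dict:
    agg = np.median if maf_agg == "median" else np.mean
    return {
        "sequence_type": name,
        "sites": sites,
        "snps": acc.snps,
        "snps_per_site": acc.snps / sites if sites else np.nan,
        "snp_maf": float(agg(acc.snp_mafs)) if acc.snp_mafs else np.nan,
        "indels": acc.indels,
        "indels_per_site": acc.indels / sites if sites else np.nan,
        "indel_maf": float(agg(acc.indel_mafs)) if acc.indel_mafs else np.nan,
    }


def _tabulate(
    variants: Iterable[FilteredVariant],
    partition: CategoryPartition,
    mask: np.ndarray | None,
    cds_mode: str,
    maf_agg: str,
    include_copy_rows: bool,
) -> pd.DataFrame:
    func_acc = {f: _Acc() for f in Functional}
    copy_acc = {c: _Acc() for c in CopyLayer}
    total_acc = _Acc()
    for v in variants:
        if not v.pass_filter:
            continue
        pos0 = v.pos - 1
        if mask is not None and not mask[pos0]:
            continue
        func, copy, _ = assign_category(v, partition, cds_mode)
        func_acc[func].add(v)
        copy_acc[copy].add(v)
        total_acc.add(v)

    in_mask = slice(None) if mask is None else mask
    func_arr = partition.functional[in_mask]
    copy_arr = partition.copy_layer[in_mask]

    def n_sites(arr: np.ndarray, label: int) -> int:
        return int(np.count_nonzero(arr == label))

    pc_acc = _Acc()
    for f in (Functional.NONSYN_SITE, Functional.SYN_SITE):
        pc_acc.snps += func_acc[f].snps
        pc_acc.indels += func_acc[f].indels
        pc_acc.snp_mafs.extend(func_acc[f].snp_mafs)
        pc_acc.indel_mafs.extend(func_acc[f].indel_mafs)
    pc_sites = (n_sites(func_arr, Functional.NONSYN_SITE)
                + n_sites(func_arr, Functional.SYN_SITE))

    rows = [_row("Protein Coding", pc_sites, pc_acc, maf_agg)]
    for f in Functional:
        rows.append(_row(_FUNC_ROW[f], n_sites(func_arr, f), func_acc[f], maf_agg))
    if include_copy_rows:
        rows.append(_row("Single-copy region",
                         n_sites(copy_arr, CopyLayer.SINGLE_COPY),
                         copy_acc[CopyLayer.SINGLE_COPY], maf_agg))
        rows.append(_row("Repeat", n_sites(copy_arr, CopyLayer.REPEAT),
                         copy_acc[CopyLayer.REPEAT], maf_agg))
    rows.append(_row("Total", int(func_arr.size), total_acc, maf_agg))
    df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    order = [r for r in ROW_ORDER if r in set(df["sequence_type"])]
    return df.set_index("sequence_type").loc[list(order)].reset_index()


def compute_category_stats(
    variants: Iterable[FilteredVariant],
    partition: CategoryPartition,
    cds_mode: str = "site",
    maf_agg: str = "mean",
) -> pd.DataFrame:
    """One row per functional label plus Protein Coding, copy-layer and Total."""
    return _tabulate(list(variants), partition, None, cds_mode, maf_agg,
                     include_copy_rows=True)


def structural_stats(
    variants: Iterable[FilteredVariant],
    partition: CategoryPartition,
    cds_mode: str = "site",
    maf_agg: str = "mean",
) -> pd.DataFrame:
    """Functional-category tables restricted to the LSC, IR and SSC strata.

    IRA and IRB merge into a single IR stratum; denominators are the
    stratum-restricted category lengths.
    """
    if not np.any(partition.structural != Structural.NONE):
        log.warning("structural layer not assigned; empty structural stats")
        return pd.DataFrame(columns=("region",) + STATS_COLUMNS)
    variants = list(variants)
    strata = {
        "LSC": partition.structural == Structural.LSC,
        "IR": np.isin(partition.structural, (Structural.IRA, Structural.IRB)),
        "SSC": partition.structural == Structural.SSC,
    }
    frames = []
    for region, mask in strata.items():
        df = _tabulate(variants, partition, mask, cds_mode, maf_agg,
                       include_copy_rows=False)
        df.insert(0, "region", region)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def neutrality_ratios(
    stats: pd.DataFrame,
    bands: tuple[float, float] = (0.8, 1.25),
) -> pd.DataFrame:
    """Each functional category's SNP abundance over the intergenic baseline.

    Categories with ratio < bands[0] are 'below baseline', within the band
    'near baseline', above bands[1] 'above baseline'.  All ratios are NA
    when the intergenic abundance is zero.
    """
    by_type = stats.set_index("sequence_type")
    baseline = float(by_type.loc["Intergenic", "snps_per_site"])
    rows = []
    for f in Functional:
        name = _FUNC_ROW[f]
        if name == "Intergenic" or name not in by_type.index:
            continue
        abund = by_type.loc[name, "snps_per_site"]
        if baseline == 0 or not np.isfinite(baseline):
            ratio, label = np.nan, "NA"
        elif not np.isfinite(abund):
            ratio, label = np.nan, "NA"
        else:
            ratio = float(abund) / baseline
            label = ("below baseline" if ratio < bands[0]
                     else "above baseline" if ratio > bands[1]
                     else "near baseline")
        rows.append({"sequence_type": name, "ratio": ratio,
                     "classification": label})
    return pd.DataFrame(rows, columns=["sequence_type", "ratio",
                                       "classification"])


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("snps_per_site", "indels_per_site", "snp_maf", "indel_maf"):
        if col in out:
            out[col] = out[col].round(4)
    return out


def write_report(
    stats: pd.DataFrame,
    tstv: dict,
    out_dir: str | Path,
    structural: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the category, structural and Ts/Tv summary TSVs.

    Abundances and MAFs are rounded to 4 decimal places in the files;
    full precision stays in memory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["category_stats"] = out_dir / "category_stats.tsv"
    _rounded(stats).to_csv(paths["category_stats"], sep="\t", index=False,
                           na_rep="NA")
    if structural is not None and not structural.empty:
        paths["structural_stats"] = out_dir / "structural_stats.tsv"
        _rounded(structural).to_csv(paths["structural_stats"], sep="\t",
                                    index=False, na_rep="NA")
    n = tstv["n_biallelic"]
    summary = pd.DataFrame([{
        "n_biallelic": n,
        "transitions": tstv["transitions"],
        "transversions": tstv["transversions"],
        "ts_pct": round(100.0 * tstv["transitions"] / n, 2) if n else np.nan,
        "tv_pct": round(100.0 * tstv["transversions"] / n, 2) if n else np.nan,
        "ratio": round(tstv["ratio"], 2) if tstv["ratio"] is not None else "NA",
    }])
    paths["tstv_summary"] = out_dir / "tstv_summary.tsv"
    summary.to_csv(paths["tstv_summary"], sep="\t", index=False, na_rep="NA")
    return paths
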