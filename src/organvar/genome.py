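"""Annotated organelle genome model and the per-position three-layer partition.

The genome is a (usually circular) nucleotide sequence plus a validated
feature set.  Every position is labelled in three orthogonal layers:

* functional — NONSYN_SITE / SYN_SITE (CDS, split by codon degeneracy),
  RRNA, TRNA, PSEUDOGENE, INTRON, INTERGENIC;
* copy       — SINGLE_COPY / REPEAT;
* structural — LSC / SSC / IRA / IRB / NONE (plastid quadripartite layout).

The layer label counts are the denominators of every per-site substitution
abundance downstream.  Coordinates are 0-based half-open internally; GFF3
(1-based inclusive) and BED (0-based half-open) apply at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .degeneracy import (
    NONSYN_SITE,
    SYN_SITE,
    GeneticCode,
    Mode,
    STANDARD_CODE,
    classify_cds_sites,
)

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class Functional(IntEnum):
    NONSYN_SITE = 0
    SYN_SITE = 1
    RRNA = 2
    TRNA = 3
    PSEUDOGENE = 4
    INTRON = 5
    INTERGENIC = 6


class CopyLayer(IntEnum):
    SINGLE_COPY = 0
    REPEAT = 1


class Structural(IntEnum):
    NONE = 0
    LSC = 1
    SSC = 2
    IRA = 3
    IRB = 4


#: functional categories painted from lowest to highest precedence; CDS wins.
DEFAULT_PRECEDENCE = ("CDS", "rRNA", "tRNA", "pseudogene", "intron")

_GFF_KIND = {
    "gene": "gene",
    "CDS": "CDS",
    "exon": "exon",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "pseudogene": "pseudogene",
    "repeat_region": "repeat",
    "repeat": "repeat",
    "inverted_repeat": "IR",
}


@dataclass
class Feature:
    """A genomic feature as one or more half-open intervals.

    ``parts`` are kept in strand-aware transcription order (ascending start
    on ``+``, descending on ``-``).  A part with start >= end wraps the
    origin of a circular genome.
    """

    kind: str
    strand: str
    parts: list[Interval]
    id: str
    parent: str | None = None
    phases: list[int] | None = None
    non_canonical: bool = False

    def genomic_parts(self, length: int) -> list[Interval]:
        """Linear (non-wrapping) intervals covered by this feature."""
        out: list[Interval] = []
        for start, end in self.parts:
            if start < end:
                out.append((start, end))
            else:  # wraps the origin
                out.append((start, length))
                if end > 0:
                    out.append((0, end))
        return out

    def span_length(self, length: int) -> int:
        return sum(e - s for s, e in self.genomic_parts(length))


@dataclass
class AnnotatedGenome:
    seq_id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def validate(self) -> None:
        for f in self.features:
            for start, end in f.parts:
                if not (0 <= start < self.length and 0 < end <= self.length):
                    raise ValueError(
                        f"feature {f.id}: interval ({start}, {end}) outside "
                        f"[0, {self.length})"
                    )
                if start >= end and not self.circular:
                    raise ValueError(
                        f"feature {f.id} wraps the origin of a linear genome"
                    )


def load_genome(fasta_path: str | Path, seq_id: str | None = None,
                circular: bool = True) -> AnnotatedGenome:
    """Load a reference genome from FASTA (first record unless seq_id given)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if seq_id is not None:
        matches = [r for r in records if r.id == seq_id]
        if not matches:
            raise ValueError(f"record {seq_id!r} not found in {fasta_path}")
        record = matches[0]
    else:
        record = records[0]
    seq = str(record.seq).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        offset = min(seq.index(c) for c in bad)
        raise ValueError(
            f"illegal character {seq[offset]!r} at position {offset + 1} "
            f"of record {record.id}"
        )
    return AnnotatedGenome(seq_id=record.id, sequence=seq, circular=circular)


def load_annotation(gff_path: str | Path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Populate genome features from a GFF3 file.

    GFF3 1-based inclusive coordinates become 0-based half-open.  CDS
    records are grouped per parent gene into a single multi-part feature,
    parts ordered in transcription order; total CDS length not a multiple
    of 3 (after phase adjustment) flags the feature non-canonical.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    cds_groups: dict[str, list[gffutils.Feature]] = {}
    for rec in db.all_features():
        kind = _GFF_KIND.get(rec.featuretype)
        if kind is None:
            log.debug("skipping unhandled feature type %s", rec.featuretype)
            continue
        start, end = rec.start - 1, rec.end  # to 0-based half-open
        if end > genome.length:
            if not genome.circular:
                raise ValueError(
                    f"feature {rec.id} interval ({rec.start}, {rec.end}) exceeds "
                    f"genome length {genome.length} on a non-circular genome"
                )
            end -= genome.length  # wraps the origin
        if kind == "CDS":
            parent = (rec.attributes.get("Parent") or [rec.id])[0]
            cds_groups.setdefault(parent, []).append(rec)
            continue
        features.append(
            Feature(
                kind=kind,
                strand=rec.strand if rec.strand in "+-" else "+",
                parts=[(start, end)],
                id=rec.id or f"{kind}_{start}",
                parent=(rec.attributes.get("Parent") or [None])[0],
            )
        )
    for parent, recs in cds_groups.items():
        strand = recs[0].strand if recs[0].strand in "+-" else "+"
        recs.sort(key=lambda r: r.start, reverse=(strand == "-"))
        parts = [(r.start - 1, r.end) for r in recs]
        phases = [int(r.frame) if r.frame not in (None, ".") else 0 for r in recs]
        total = sum(e - s for s, e in parts)
        feat = Feature(
            kind="CDS",
            strand=strand,
            parts=parts,
            id=f"cds:{parent}",
            parent=parent,
            phases=phases,
            non_canonical=(total - (phases[0] if phases else 0)) % 3 != 0,
        )
        if feat.non_canonical:
            log.warning("CDS of %s is not a multiple of 3; flagged non-canonical", parent)
        features.append(feat)
    genome.features = features
    genome.validate()
    return genome


def read_bed(path: str | Path) -> list[Interval]:
    """Read 0-based half-open intervals from the first three BED columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    if df.empty:
        return []
    return [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


# ---------------------------------------------------------------------------
# CDS extraction and site classes


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_cds(genome: AnnotatedGenome, feat: Feature) -> tuple[str, list[int]]:
    """Spliced coding sequence (mRNA sense) and its genomic positions.

    Positions are listed in transcription order, so ``positions[i]`` is the
    genomic coordinate of CDS base ``i``.
    """
    linear = sorted(feat.genomic_parts(genome.length))
    positions: list[int] = []
    for start, end in linear:
        positions.extend(range(start, end))
    seq = "".join(genome.sequence[i] for i in positions)
    if feat.strand == "-":
        positions.reverse()
        seq = _revcomp(seq)
    phase = feat.phases[0] if feat.phases else 0
    if phase:
        seq = seq[phase:]
        positions = positions[phase:]
    return seq, positions


def cds_site_classes(
    genome: AnnotatedGenome,
    mode: Mode = "fourfold",
    code: GeneticCode = STANDARD_CODE,
) -> tuple[dict[int, Functional], dict[int, tuple[str, int, str]]]:
    """Per-genome-position synonymous/nonsynonymous classes for all CDS.

    Returns (classes, context) where classes maps genomic position ->
    Functional.SYN_SITE / Functional.NONSYN_SITE and context maps position ->
    (codon, offset-in-codon, strand) for substitution-effect classification.
    Overlapping CDS assignments resolve to NONSYN_SITE (conservative).
    """
    classes: dict[int, Functional] = {}
    context: dict[int, tuple[str, int, str]] = {}
    for feat in genome.features_of("CDS"):
        seq, positions = spliced_cds(genome, feat)
        if len(seq) % 3 != 0:
            log.warning(
                "CDS %s length %d not a multiple of 3; all positions counted "
                "nonsynonymous", feat.id, len(seq),
            )
            for pos in positions:
                classes[pos] = Functional.NONSYN_SITE
            continue
        sc = classify_cds_sites(seq, mode="fourfold" if mode == "fractional" else mode,
                                code=code, strict=False)
        for i, pos in enumerate(positions):
            label = (Functional.SYN_SITE if sc.classes[i] == SYN_SITE
                     else Functional.NONSYN_SITE)
            if pos in classes and classes[pos] != label:
                label = Functional.NONSYN_SITE  # conflicting overlap: conservative
            classes[pos] = label
            codon = seq[3 * (i // 3): 3 * (i // 3) + 3]
            context[pos] = (codon, i % 3, feat.strand)
    return classes, context


def per_gene_site_counts(
    genome: AnnotatedGenome,
    mode: Mode = "fourfold",
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-gene synonymous/nonsynonymous site totals (CLI `classify-sites`)."""
    rows = []
    for feat in genome.features_of("CDS"):
        seq, _ = spliced_cds(genome, feat)
        if len(seq) % 3 != 0:
            rows.append({"gene": feat.parent or feat.id, "nonsyn_sites": len(seq),
                         "syn_sites": 0.0, "non_canonical": True})
            continue
        sc = classify_cds_sites(seq, mode=mode, code=code, strict=False)
        syn = sc.syn_sites
        rows.append({"gene": feat.parent or feat.id,
                     "nonsyn_sites": len(seq) - syn,
                     "syn_sites": syn, "non_canonical": False})
    return pd.DataFrame(rows, columns=["gene", "nonsyn_sites", "syn_sites",
                                       "non_canonical"])


# ---------------------------------------------------------------------------
# Introns and partition


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def derive_introns(genome: AnnotatedGenome) -> list[Interval]:
    """Introns = each gene span minus the union of its CDS/exon parts."""
    children: dict[str, list[Feature]] = {}
    for f in genome.features_of("CDS", "exon"):
        if f.parent is not None:
            children.setdefault(f.parent, []).append(f)
    introns: list[Interval] = []
    L = genome.length
    for gene in genome.features_of("gene"):
        kids = children.get(gene.id)
        if not kids:
            continue
        covered = np.zeros(L, dtype=bool)
        for kid in kids:
            for s, e in kid.genomic_parts(L):
                covered[s:e] = True
        for s, e in gene.genomic_parts(L):
            inside = np.flatnonzero(~covered[s:e])
            if inside.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(inside) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [inside.size - 1]))
            for a, b in zip(run_starts, run_ends):
                introns.append((s + int(inside[a]), s + int(inside[b]) + 1))
    return _merge_intervals(introns)


@dataclass
class CategoryPartition:
    """Per-position labels in the three orthogonal layers."""

    functional: np.ndarray  # int8 of Functional
    copy_layer: np.ndarray  # int8 of CopyLayer
    structural: np.ndarray  # int8 of Structural
    cds_context: dict[int, tuple[str, int, str]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return int(self.functional.size)


def _paint(arr: np.ndarray, intervals: Iterable[Interval], value: int,
           length: int, kind: str, background: int) -> None:
    for part in intervals:
        segs = [part] if part[0] < part[1] else [(part[0], length), (0, part[1])]
        for s, e in segs:
            overlap = int(np.count_nonzero(arr[s:e] != background))
            if overlap:
                log.warning(
                    "%d positions of %s interval (%d, %d) overlap a lower-"
                    "precedence category; overwritten", overlap, kind, s, e)
            arr[s:e] = value


def build_partition(
    genome: AnnotatedGenome,
    site_classes: dict[int, Functional] | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    repeats: Sequence[Interval] | None = None,
    cds_context: dict[int, tuple[str, int, str]] | None = None,
) -> CategoryPartition:
    """Assign every position one label per layer.

    The functional layer is painted from lowest to highest precedence
    (default intron < pseudogene < tRNA < rRNA < CDS) over an INTERGENIC
    background; CDS positions are split into SYN/NONSYN via ``site_classes``
    (computed with fourfold-degeneracy defaults when omitted).  The copy
    layer is REPEAT where any repeat interval covers the position,
    independent of the functional layer.
    """
    L = genome.length
    if site_classes is None:
        site_classes, cds_context = cds_site_classes(genome)
    functional = np.full(L, Functional.INTERGENIC, dtype=np.int8)
    painters = {
        "intron": lambda: derive_introns(genome),
        "pseudogene": lambda: [p for f in genome.features_of("pseudogene")
                               for p in f.parts],
        "tRNA": lambda: [p for f in genome.features_of("tRNA") for p in f.parts],
        "rRNA": lambda: [p for f in genome.features_of("rRNA") for p in f.parts],
        "CDS": lambda: [p for f in genome.features_of("CDS") for p in f.parts],
    }
    label_of = {
        "intron": Functional.INTRON,
        "pseudogene": Functional.PSEUDOGENE,
        "tRNA": Functional.TRNA,
        "rRNA": Functional.RRNA,
        "CDS": Functional.NONSYN_SITE,  # refined by site_classes below
    }
    for cat in reversed(list(precedence)):
        _paint(functional, painters[cat](), label_of[cat], L, cat,
               Functional.INTERGENIC)
    if site_classes:
        pos = np.fromiter(site_classes.keys(), dtype=np.int64)
        lab = np.fromiter((int(v) for v in site_classes.values()), dtype=np.int8)
        cds_mask = functional[pos] == Functional.NONSYN_SITE
        functional[pos[cds_mask]] = lab[cds_mask]

    copy_layer = np.full(L, CopyLayer.SINGLE_COPY, dtype=np.int8)
    repeat_ivs = list(repeats or []) + [p for f in genome.features_of("repeat")
                                        for p in f.parts]
    for part in repeat_ivs:
        segs = [part] if part[0] < part[1] else [(part[0], L), (0, part[1])]
        for s, e in segs:
            copy_layer[s:e] = CopyLayer.REPEAT

    structural = np.full(L, Structural.NONE, dtype=np.int8)
    return CategoryPartition(functional, copy_layer, structural,
                             cds_context or {})


def assign_structural_regions(
    partition: CategoryPartition,
    ir_a: Interval | None = None,
    ir_b: Interval | None = None,
    genome: AnnotatedGenome | None = None,
) -> CategoryPartition:
    """Label IRA/IRB and the two single-copy arcs (longer LSC, shorter SSC).

    Mitochondrial partitions are left all-NONE by passing no IR intervals.
    The reverse-complement equivalence of the two IRs is checked only when
    the genome is supplied, and produces a warning, not an error.
    """
    if ir_a is None and ir_b is None:
        return partition
    if ir_a is None or ir_b is None:
        raise ValueError("both IR intervals are required (or neither)")
    L = partition.length
    structural = np.full(L, Structural.NONE, dtype=np.int8)

    def segs(iv: Interval) -> list[Interval]:
        return [iv] if iv[0] < iv[1] else [(iv[0], L), (0, iv[1])]

    for s, e in segs(ir_a):
        structural[s:e] = Structural.IRA
    for s, e in segs(ir_b):
        if np.any(structural[s:e] == Structural.IRA):
            raise ValueError("IR intervals overlap")
        structural[s:e] = Structural.IRB
    len_a = int(np.count_nonzero(structural == Structural.IRA))
    len_b = int(np.count_nonzero(structural == Structural.IRB))
    if len_a != len_b:
        log.warning("IR lengths differ (%d vs %d); labels still assigned",
                    len_a, len_b)
    if genome is not None:
        seq_a = "".join(genome.sequence[s:e] for s, e in segs(ir_a))
        seq_b = "".join(genome.sequence[s:e] for s, e in segs(ir_b))
        if seq_a != _revcomp(seq_b):
            log.warning("IR intervals are not reverse-complement identical")

    # the complement of the two IRs on the circle is (at most) two arcs
    non_ir = structural == Structural.NONE
    idx = np.flatnonzero(non_ir)
    runs: list[np.ndarray] = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        pieces = np.split(idx, breaks + 1)
        if len(pieces) > 1 and pieces[0][0] == 0 and pieces[-1][-1] == L - 1:
            pieces[0] = np.concatenate((pieces[-1], pieces[0]))  # circular join
            pieces.pop()
        runs = sorted(pieces, key=len, reverse=True)
    for i, run in enumerate(runs):
        structural[run] = Structural.LSC if i == 0 else Structural.SSC
    partition.structural = structural
    return partition


def category_lengths(partition: CategoryPartition) -> pd.DataFrame:
    """Per-layer label counts (the Sites denominators)."""
    rows = []
    for label in Functional:
        rows.append({"layer": "functional", "label": label.name,
                     "sites": int(np.count_nonzero(partition.functional == label))})
    for label in CopyLayer:
        rows.append({"layer": "copy", "label": label.name,
                     "sites": int(np.count_nonzero(partition.copy_layer == label))})
    for label in Structural:
        rows.append({"layer": "structural", "label": label.name,
                     "sites": int(np.count_nonzero(partition.structural == label))})
    ir = int(np.count_nonzero(np.isin(partition.structural,
                                      (Structural.IRA, Structural.IRB))))
    rows.append({"layer": "structural", "label": "IR", "sites": ir})
    return pd.DataFrame(rows)


def write_partition_tsv(partition: CategoryPartition, path: str | Path) -> None:
    """Per-position export: position (1-based), functional, copy, structural."""
    df = pd.DataFrame({
        "position": np.arange(1, partition.length + 1),
        "functional": [Functional(v).name for v in partition.functional],
        "copy_layer": [CopyLayer(v).name for v in partition.copy_layer],
        "structural": [Structural(v).name for v in partition.structural],
    })
    df.to_csv(path, sep="\t", index=False)


def write_category_summary(partition: CategoryPartition, path: str | Path) -> None:
    category_lengths(partition).to_csv(path, sep="\t", index=False)
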