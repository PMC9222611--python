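"""Genome model, intron derivation and the three-layer partition."""

import numpy as np
import pytest

from organvar.degeneracy import translate
from organvar.genome import (
    AnnotatedGenome,
    CopyLayer,
    Feature,
    Functional,
    Structural,
    assign_structural_regions,
    build_partition,
    category_lengths,
    cds_site_classes,
    derive_introns,
    load_annotation,
    load_genome,
    spliced_cds,
)


# ---------------------------------------------------------------------------
# I/O


def test_load_genome_basics(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">s1\nACGTACGT\n")
    g = load_genome(p)
    assert g.length == 8 and g.seq_id == "s1"
    p.write_text(">s1\nacgt\n")
    assert load_genome(p).sequence == "ACGT"
    p.write_text(">s1\nACXT\n")
    with pytest.raises(ValueError, match="illegal character"):
        load_genome(p)
    p.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        load_genome(p)


def test_gff_coordinates_become_half_open(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">s1\n" + "A" * 50 + "\n")
    gff = tmp_path / "a.gff3"
    gff.write_text("##gff-version 3\n"
                   "s1\t.\ttRNA\t11\t40\t.\t+\t.\tID=trnX\n")
    genome = load_annotation(gff, load_genome(fa))
    (feat,) = genome.features_of("tRNA")
    assert feat.parts == [(10, 40)]
    assert feat.kind == "tRNA"


def test_interval_beyond_linear_genome_rejected(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">s1\n" + "A" * 20 + "\n")
    gff = tmp_path / "a.gff3"
    gff.write_text("s1\t.\ttRNA\t10\t30\t.\t+\t.\tID=trnX\n")
    with pytest.raises(ValueError, match="exceeds genome length"):
        load_annotation(gff, load_genome(fa, circular=False))


def test_minus_strand_cds_transcription_order_and_translation():
    """Two-part minus-strand gene: spliced CDS matches the hand translation."""
    from Bio.Seq import Seq
    mrna = "ATGAAATTTTAA"  # M K F *
    e1, e2, intron = mrna[:5], mrna[5:], "GGGGG"
    block = str(Seq(e1 + intron + e2).reverse_complement())
    seq = "C" * 10 + block + "C" * 13
    # e2 occupies genomic [10, 17), e1 genomic [22, 27); transcription order
    # for '-' lists parts descending by start
    feat = Feature(kind="CDS", strand="-", parts=[(22, 27), (10, 17)],
                   id="cds:g1", parent="g1", phases=[0, 1])
    genome = AnnotatedGenome(seq_id="t", sequence=seq, features=[feat])
    cds, positions = spliced_cds(genome, feat)
    assert cds == mrna
    assert translate(cds) == "MKF*"
    assert positions[0] == 26  # transcription starts at the rightmost base


# ---------------------------------------------------------------------------
# Introns


def _gene_with_cds(parts, gene_span, strand="+"):
    gene = Feature(kind="gene", strand=strand, parts=[gene_span], id="g1")
    cds = Feature(kind="CDS", strand=strand, parts=list(parts), id="cds:g1",
                  parent="g1", phases=[0] * len(parts))
    return [gene, cds]


def test_derive_introns_examples():
    seq = "A" * 120
    genome = AnnotatedGenome("t", seq, features=_gene_with_cds(
        [(0, 30), (60, 100)], (0, 100)))
    assert derive_introns(genome) == [(30, 60)]

    genome = AnnotatedGenome("t", seq, features=_gene_with_cds(
        [(10, 40)], (10, 40)))
    assert derive_introns(genome) == []


def test_introns_of_separate_genes_are_independent():
    """Brute-force per-position membership over two non-overlapping genes."""
    seq = "A" * 200
    feats = _gene_with_cds([(0, 30), (60, 90)], (0, 90))
    g2 = Feature(kind="gene", strand="+", parts=[(100, 180)], id="g2")
    c2 = Feature(kind="CDS", strand="+", parts=[(100, 120), (150, 180)],
                 id="cds:g2", parent="g2", phases=[0, 0])
    genome = AnnotatedGenome("t", seq, features=feats + [g2, c2])
    introns = derive_introns(genome)
    covered = set()
    for s, e in introns:
        covered.update(range(s, e))
    expected = set()
    for gene_span, cds_parts in [((0, 90), [(0, 30), (60, 90)]),
                                 ((100, 180), [(100, 120), (150, 180)])]:
        inside = set(range(*gene_span))
        for s, e in cds_parts:
            inside -= set(range(s, e))
        expected |= inside
    assert covered == expected


# ---------------------------------------------------------------------------
# Partition

ORF30 = "ATG" + "GCTAAAGGGTTCCCTGATCATGTT" + "TAA"  # 30 bp, no internal stop


def _toy_genome():
    seq = ("C" * 10 + ORF30 + "C" * 10 + "G" * 10 + "C" * 40)
    feats = _gene_with_cds([(10, 40)], (10, 40))
    feats.append(Feature(kind="rRNA", strand="+", parts=[(50, 60)], id="rrn1"))
    return AnnotatedGenome("toy", seq, features=feats)


def test_partition_toy_functional_lengths():
    genome = _toy_genome()
    part = build_partition(genome)
    counts = {f: int(np.count_nonzero(part.functional == f)) for f in Functional}
    assert counts[Functional.NONSYN_SITE] + counts[Functional.SYN_SITE] == 30
    assert counts[Functional.RRNA] == 10
    assert counts[Functional.INTERGENIC] == 60
    assert sum(counts.values()) == genome.length


def test_repeat_layer_is_orthogonal_to_functional():
    genome = _toy_genome()
    part = build_partition(genome, repeats=[(0, 50)])
    assert int(np.count_nonzero(part.copy_layer == CopyLayer.REPEAT)) == 50
    # functional layer unchanged by the repeat overlay
    ref = build_partition(genome)
    assert np.array_equal(part.functional, ref.functional)
    # position inside both rRNA and a repeat keeps both labels
    part2 = build_partition(genome, repeats=[(50, 55)])
    assert part2.functional[52] == Functional.RRNA
    assert part2.copy_layer[52] == CopyLayer.REPEAT


def test_partition_invariant_under_feature_order(small_fixture):
    genome = small_fixture["result"].genome
    ref = build_partition(genome)
    rng = np.random.default_rng(5)
    for _ in range(3):
        shuffled = list(genome.features)
        rng.shuffle(shuffled)
        g2 = AnnotatedGenome(genome.seq_id, genome.sequence, genome.circular,
                             shuffled)
        part = build_partition(g2)
        assert np.array_equal(part.functional, ref.functional)
        assert np.array_equal(part.copy_layer, ref.copy_layer)


def naive_functional_labels(genome):
    """Independent per-position membership scan (the brute-force oracle)."""
    L = genome.length
    member = {k: set() for k in ("CDS", "rRNA", "tRNA", "pseudogene")}
    for kind in member:
        for f in genome.features_of(kind):
            for s, e in f.genomic_parts(L):
                member[kind].update(range(s, e))
    intron = set()
    kids = {}
    for f in genome.features_of("CDS", "exon"):
        if f.parent:
            kids.setdefault(f.parent, []).append(f)
    for gene in genome.features_of("gene"):
        if gene.id not in kids:
            continue
        inside = set()
        for s, e in gene.genomic_parts(L):
            inside.update(range(s, e))
        for kid in kids[gene.id]:
            for s, e in kid.genomic_parts(L):
                inside -= set(range(s, e))
        intron |= inside
    classes, _ = cds_site_classes(genome)
    labels = np.empty(L, dtype=np.int8)
    for p in range(L):
        if p in member["CDS"]:
            labels[p] = classes.get(p, Functional.NONSYN_SITE)
        elif p in member["rRNA"]:
            labels[p] = Functional.RRNA
        elif p in member["tRNA"]:
            labels[p] = Functional.TRNA
        elif p in member["pseudogene"]:
            labels[p] = Functional.PSEUDOGENE
        elif p in intron:
            labels[p] = Functional.INTRON
        else:
            labels[p] = Functional.INTERGENIC
    return labels


def test_partition_matches_naive_oracle(small_fixture):
    genome = small_fixture["result"].genome
    part = build_partition(genome)
    assert np.array_equal(part.functional, naive_functional_labels(genome))


def test_circular_feature_equals_linearized_rotation():
    rng = np.random.default_rng(2)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    wrap = AnnotatedGenome("c", seq, circular=True, features=[
        Feature(kind="rRNA", strand="+", parts=[(90, 10)], id="r")])
    rotated = AnnotatedGenome("c", seq[50:] + seq[:50], circular=True,
                              features=[Feature(kind="rRNA", strand="+",
                                                parts=[(40, 60)], id="r")])
    cw = category_lengths(build_partition(wrap))
    cr = category_lengths(build_partition(rotated))
    fw = cw[cw.layer == "functional"].set_index("label")["sites"]
    fr = cr[cr.layer == "functional"].set_index("label")["sites"]
    assert fw.equals(fr)
    assert fw["RRNA"] == 20


# ---------------------------------------------------------------------------
# Structural regions


def _blank_partition(length):
    genome = AnnotatedGenome("p", "A" * length)
    return build_partition(genome)


def test_structural_arcs_longer_lsc_shorter_ssc():
    part = _blank_partition(1000)
    assign_structural_regions(part, (100, 200), (700, 800))
    counts = {s: int(np.count_nonzero(part.structural == s)) for s in Structural}
    assert counts[Structural.IRA] == 100 and counts[Structural.IRB] == 100
    # complement of the IRs on the circle: arcs of 500 and 300 bp
    assert counts[Structural.LSC] == 500
    assert counts[Structural.SSC] == 300
    assert counts[Structural.NONE] == 0


def test_structural_none_without_irs():
    part = _blank_partition(500)
    assign_structural_regions(part)
    assert np.all(part.structural == Structural.NONE)


def test_unequal_irs_warn_but_assign(caplog):
    part = _blank_partition(1000)
    with caplog.at_level("WARNING"):
        assign_structural_regions(part, (100, 200), (700, 850))
    assert "IR lengths differ" in caplog.text
    counts = np.bincount(part.structural, minlength=5)
    assert counts[Structural.IRA] == 100 and counts[Structural.IRB] == 150
    assert counts.sum() == 1000 and counts[Structural.NONE] == 0


def test_overlapping_irs_rejected():
    part = _blank_partition(1000)
    with pytest.raises(ValueError, match="overlap"):
        assign_structural_regions(part, (100, 300), (250, 400))


def test_category_lengths_sum_to_genome(small_fixture):
    part = small_fixture["result"].partition
    cl = category_lengths(part)
    func = cl[cl.layer == "functional"]["sites"].sum()
    copy = cl[cl.layer == "copy"]["sites"].sum()
    assert func == part.length == copy
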