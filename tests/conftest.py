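import numpy as np
import pytest

from organvar.filtering import FilteredVariant, classify_substitution
from organvar.pipeline import run_pipeline
from organvar.simulate import FeaturePlan, SimulationConfig, end_to_end_fixture


def make_variant(pos, ref="A", alt="G", var_type=None, maf=0.1,
                 seq_id="chr", pass_filter=True, extra_alts=(),
                 genotypes=None):
    """FilteredVariant factory for table construction in tests."""
    alts = (alt,) + tuple(extra_alts)
    if var_type is None:
        var_type = "SNP" if len(ref) == 1 and all(len(a) == 1 for a in alts) \
            else "INDEL"
    biallelic = len(alts) == 1
    subst = "NA"
    if var_type == "SNP" and biallelic:
        subst = classify_substitution(ref, alt)
    return FilteredVariant(
        seq_id=seq_id, pos=pos, ref=ref, alts=alts, qual=100.0, qd=30.0,
        fs=1.0, mq=50.0, genotypes=genotypes or [0, 1], var_type=var_type,
        biallelic=biallelic, subst_type=subst, maf=maf,
        pass_filter=pass_filter)


SMALL_PLAN = FeaturePlan(
    n_cds=2, cds_length=(300, 600), introns_per_cds=(0, 2),
    intron_length=(100, 200), n_rrna=1, rrna_length=(300, 400), n_trna=3,
    n_pseudogene=1, pseudogene_length=(200, 300), n_repeat_pairs=1,
    repeat_length=(200, 400))


def small_config(seed=3, **kw):
    from organvar.simulate import DepthPlan
    kw.setdefault("depth", DepthPlan(cnv_segments=[(5_000, 6_500, 2.0)]))
    return SimulationConfig(seed=seed, genome_length=9_000, n_samples=6,
                            features=SMALL_PLAN, **kw)


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """Default-condition synthetic data set plus the pipeline result."""
    cfg = SimulationConfig(seed=0)
    out = tmp_path_factory.mktemp("fixture")
    fx = end_to_end_fixture(cfg, out)
    result = run_pipeline(fx["fasta"], fx["gff"], fx["vcf"],
                          repeats_bed=fx["repeats_bed"])
    return {"cfg": cfg, "fx": fx, "result": result}


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A <= 10 kb genome for brute-force oracle comparisons."""
    cfg = small_config()
    out = tmp_path_factory.mktemp("small")
    fx = end_to_end_fixture(cfg, out)
    result = run_pipeline(fx["fasta"], fx["gff"], fx["vcf"],
                          repeats_bed=fx["repeats_bed"])
    return {"cfg": cfg, "fx": fx, "result": result}
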