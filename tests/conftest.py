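import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">
##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t1000\trs1\tA\tG\t.\tPASS\tTYPED\tGT\t0/1\t1/1\t0/0
2\t2000\trs2\tC\tT\t.\tPASS\tR2=0.87\tGT:DS\t0/0:1.73\t0/1:0.5\t./.:.
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture
def pheno_tsv(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "sample_id\tsex\tphenotype\tcohort\n"
        "S1\tmale\tcase\tunassigned\n"
        "S2\tfemale\tcontrol\tunassigned\n"
        "S3\t\tcase\tunassigned\n"
    )
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-signal cohort shared by slower tests."""
    from prstrat.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_cases=600,
        n_controls=1200,
        n_null_variants=250,
        baseline_prevalence=0.01,
        seed=42,
    )
    return simulate_cohort(cfg)
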