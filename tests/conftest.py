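"""Shared fixtures: small simulated cohorts and hand-written VCF/GFF3 inputs."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from poolscan.simulate import SimulationConfig, SweepSpec, simulate_cohort, write_simulated_cohort

# Tiny hand-written multi-pool VCF: 4 records, one multi-allelic, one below
# each filter threshold in pool-specific ways.
FIXTURE_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##INFO=<ID=ANN,Number=.,Type=String,Description="effect|impact|gene">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpoolA\tpoolB\tpoolC
    chr1\t100\t.\tA\tG\t60\t.\tANN=missense_variant|MODERATE|G1\tDP:AD\t14:10,4\t4:1,3\t14:13,1
    chr1\t200\t.\tC\tT\t29\t.\t.\tDP:AD\t14:9,5\t14:9,5\t14:9,5
    chr1\t300\t.\tG\tA,T\t60\t.\t.\tDP:AD\t14:6,4,4\t14:6,4,4\t14:6,4,4
    chr1\t400\t.\tT\tC\t60\t.\tANN=stop_gained|HIGH|G2\tDP:AD\t20:10,10\t20:20,0\t20:18,2
    """
)

FIXTURE_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=G1;Name=G1
    chr1\ttest\tgene\t5001\t8000\t.\t-\t.\tID=G2;Name=G2
    chr2\ttest\tgene\t1\t500\t.\t+\t.\tID=G3;Name=G3
    """
)


@pytest.fixture(scope="session")
def fixture_vcf(tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("fixtures") / "pools.vcf"
    path.write_text(FIXTURE_VCF)
    return path


@pytest.fixture(scope="session")
def fixture_gff3(tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("fixtures") / "genes.gff3"
    path.write_text(FIXTURE_GFF3)
    return path


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A 3-pool, 6 Mb cohort with one planted sweep and planted private genes."""
    defaults = dict(
        chrom_lengths={"chr1": 4_000_000, "chr2": 3_000_000, "chrX": 1_500_000},
        sweeps=[SweepSpec("chr1", 1_000_000, 1_400_000, (0,), 1.0)],
        private_missense_per_breed=20,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_config()
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_paths(tmp_path_factory, small_cohort):
    config, cohort = small_cohort
    out = tmp_path_factory.mktemp("cohort")
    return config, write_simulated_cohort(config, out, cohort=cohort)
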