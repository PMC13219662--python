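"""Shared fixtures: small simulated datasets and a hand-crafted filter VCF."""

from __future__ import annotations

import numpy as np
import pytest

import loadscape as ls
from loadscape.genotype_io import GenotypeMatrix, SiteRecord, MISSING


SMALL_CONFIG = ls.SimulationConfig(
    seed=11,
    n_sites=8_000,
    n_invariant_sites=400,
    chromosome_length=10_000_000,
    populations=(
        ls.PopulationSpec("LC", 6, 3.4e-6, 0.8, ls.ROHSpec(median_length_bp=6_000_000)),
        ls.PopulationSpec("ST", 6, 1.36e-4, 0.4, ls.ROHSpec(median_length_bp=1_500_000)),
        ls.PopulationSpec("SI", 6, 4.76e-3, 0.0),
    ),
)

OUTGROUP_SPEC = ls.OutgroupSpec(
    ("OGA1", "OGA2", "OGA3", "OGA4"), ("OGB1", "OGB2")
)
INGROUP = ["LC", "ST", "SI"]


@pytest.fixture(scope="session")
def small_dataset() -> ls.SimulatedDataset:
    return ls.simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_polarized(small_dataset):
    return ls.polarize_dataset(small_dataset.matrix, OUTGROUP_SPEC, INGROUP)


@pytest.fixture(scope="session")
def small_annotations(small_dataset, small_polarized):
    from loadscape.load_metrics import align_annotations

    return align_annotations(small_polarized, small_dataset.annotation_frame())


def make_matrix(
    genotypes,
    site_types=None,
    populations=None,
    chrom="chr01",
    start_pos=100,
    spacing=100,
    info=None,
    qual=100.0,
    positions=None,
    refs=None,
    alts=None,
    depth=None,
    gt_qual=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a genotype-code array with sane defaults."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = G.shape
    individuals = [f"S{i + 1}" for i in range(n_ind)]
    populations = populations or {s: "P" for s in individuals}
    site_types = site_types or ["snp"] * n_sites
    positions = positions or [start_pos + i * spacing for i in range(n_sites)]
    base_info = info or {
        "QD": 25.0,
        "FS": 1.0,
        "MQ": 60.0,
        "MQRankSum": 0.0,
        "ReadPosRankSum": 0.0,
    }
    sites = []
    for i in range(n_sites):
        st = site_types[i]
        sites.append(
            SiteRecord(
                chrom=chrom,
                pos=positions[i],
                ref=refs[i] if refs else "A",
                alt=(alts[i] if alts else "G") if st == "snp" else None,
                site_type=st,
                qual=qual,
                info=dict(base_info) if st == "snp" else {},
            )
        )
    depth = (
        np.asarray(depth, dtype=np.int32)
        if depth is not None
        else np.full((n_sites, n_ind), 15, dtype=np.int32)
    )
    gq = (
        np.asarray(gt_qual, dtype=np.int32)
        if gt_qual is not None
        else np.full((n_sites, n_ind), 99, dtype=np.int32)
    )
    return GenotypeMatrix(
        sites=sites,
        individuals=individuals,
        genotypes=G,
        depth=depth,
        gt_qual=gq,
        populations=populations,
    )


# ---------------------------------------------------------------------------
# crafted 20-record filter VCF: exactly 6 sites fail, one per rule
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr01,length=10000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">
##INFO=<ID=DP,Number=1,Type=Integer,Description="DP">
##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="RGQ">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""

_PASS_INFO = "QD=25;FS=1;MQ=60;MQRankSum=0;ReadPosRankSum=0;DP=60"
_GT = "0/1:15:99"
_HOM = "0/0:15:99"


def _snp(pos, qual=100, info=_PASS_INFO, gts=None):
    gts = gts or [_GT, _HOM, _HOM, _HOM]
    return f"chr01\t{pos}\t.\tA\tG\t{qual}\tPASS\t{info}\tGT:DP:GQ\t" + "\t".join(gts)


def _inv(pos):
    cells = "\t".join(["0/0:15:99"] * 4)
    return f"chr01\t{pos}\t.\tA\t.\t100\tPASS\tDP=60\tGT:DP:RGQ\t{cells}"


@pytest.fixture(scope="session")
def filter_fixture(tmp_path_factory):
    """20 sites crafted so exactly 6 fail: QUAL, QD, MQ, indel proximity,
    missingness and region mask remove one site each; 14 survive.

    Also includes boundary genotypes: DP exactly mean*2 (30) and exactly
    mean/3 (5) at a passing site, which must be retained.
    """
    rows = [
        _snp(100),                                    # pass
        _snp(200, qual=50),                           # fail: qual
        _snp(300, info="QD=1.0;FS=1;MQ=60;MQRankSum=0;ReadPosRankSum=0;DP=60"),  # fail: qd
        _snp(400),                                    # pass
        _snp(500, info="QD=25;FS=1;MQ=30;MQRankSum=0;ReadPosRankSum=0;DP=60"),   # fail: mq
        _snp(600),                                    # pass
        "chr01\t1000\t.\tATG\tA\t100\tPASS\t" + _PASS_INFO + "\tGT:DP:GQ\t"
        + "\t".join([_HOM] * 4),                      # high-quality indel (mask source)
        _snp(1005),                                   # fail: within 5 bp of indel span
        _snp(1100),                                   # pass
        _snp(1200, gts=[_GT, "./.:.:.", "./.:.:.", _HOM]),  # fail: 50% missing
        _snp(1300),                                   # fail: region mask 1290-1310
        _snp(1400, gts=["0/1:30:99", "0/1:5:99", _HOM, _HOM]),  # pass: DP bounds exclusive
        _snp(1500),
        _snp(1600),
        _inv(1700),
        _inv(1800),
        _snp(1900),
        _snp(2000),
        _snp(2100),
        _inv(2200),
        _snp(2300),
    ]
    assert len(rows) == 21  # 20 sites + 1 indel record
    d = tmp_path_factory.mktemp("filter_vcf")
    vcf = d / "crafted.vcf"
    vcf.write_text(_VCF_HEADER + "\n".join(rows) + "\n")
    pops = d / "pops.tsv"
    pops.write_text("".join(f"S{i}\tP\n" for i in range(1, 5)))
    config = ls.FilterConfig(
        excluded_region_sets={"mask": [("chr01", 1290, 1310)]}
    )
    mean_depths = {f"S{i}": 15.0 for i in range(1, 5)}
    expected_removed = {
        "qual": 1,
        "qd": 1,
        "mq": 1,
        "indel_proximity": 1,
        "missingness": 1,
        "region_mask": 1,
    }
    return {
        "vcf": vcf,
        "pops": pops,
        "config": config,
        "mean_depths": mean_depths,
        "expected_removed": expected_removed,
        "surviving_positions": {100, 400, 600, 1100, 1400, 1500, 1600, 1700,
                                1800, 1900, 2000, 2100, 2200, 2300},
    }
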