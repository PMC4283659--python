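import numpy as np
import pytest

from haplohom import GroupAssignment, HaplotypeMatrix, build_panel, calibrate

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\t.\tT\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""

TOY_GROUPS = {
    "s1_A": "EuropeanWild",
    "s1_B": "EuropeanWild",
    "s2_A": "AsianWild",
    "s2_B": "AsianWild",
}


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_groups():
    return GroupAssignment.from_pairs(TOY_GROUPS)


@pytest.fixture
def toy_matrix():
    # direct transcription of TOY_VCF
    return HaplotypeMatrix(
        "1",
        np.array([100, 200, 300]),
        np.array([[0, 0, 1], [1, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=np.int8),
        ["s1_A", "s1_B", "s2_A", "s2_B"],
    )


#: Panel sizes/length for the shared simulation fixture: large enough for
#: group means to sit within a few 1e-3 of their closed forms, small enough
#: for the whole suite to stay fast.
PANEL_SIZES = {
    "EuropeanWild": 20,
    "AsianCommercial": 20,
    "EuropeanCommercial": 16,
    "AsianWild": 12,
    "Outgroup": 4,
}


@pytest.fixture(scope="session")
def calibrated_panel():
    config = calibrate(seed=11, L=20_000, sample_sizes=dict(PANEL_SIZES))
    m, ga, truth = build_panel(config)
    return config, m, ga, truth


def random_matrix(rng, n_individuals=3, n_sites=50, chromosome="1"):
    """Small random phased panel for property tests."""
    H = 2 * n_individuals
    positions = np.cumsum(rng.integers(1, 500, size=n_sites))
    alleles = rng.integers(0, 2, size=(H, n_sites)).astype(np.int8)
    ids = [f"i{k}_{s}" for k in range(n_individuals) for s in "AB"]
    return HaplotypeMatrix(chromosome, positions, alleles, ids)
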