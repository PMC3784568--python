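import pytest

from strainsift.simulate import SimConfig, simulate_world

SMALL = dict(
    n_chromosomes=5,
    chrom_length=60_000,
    n_genes=10,
    pool_size=1500,
    n_strains=6,
    private_per_strain=50,
)


@pytest.fixture(scope="session")
def small_world():
    """One seeded synthetic world shared by read-only tests."""
    return simulate_world(SimConfig(seed=7, **SMALL))


@pytest.fixture()
def small_config():
    return SimConfig(seed=7, **SMALL)


VCF_FIXTURE = "\n".join(
    [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
        "chr1\t100\t.\tA\tG\t214\tPASS\tDP=122\tGT\t1/1",
        "chr1\t205\t.\tCTT\tC\t16.9\tPASS\tDP=5\tGT\t1/1",
        "chr2\t50\t.\tG\tT\t90\tPASS\tDP=33\tGT\t0/1",
        "chr2\t77\t.\tT\tTA,TAA\t55\tPASS\tDP=40\tGT\t1/1",
        "chr3\t9\t.\tG\tC\t77\tPASS\tNS=3\tGT\t1/1",
    ]
) + "\n"


@pytest.fixture()
def vcf_text():
    return VCF_FIXTURE
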