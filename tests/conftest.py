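import pytest

from cgrscope.genome import Genome
from cgrscope.genomic_io import canonical_sv
from cgrscope.simdata import CgrSpec, SimConfig, simulate_cohort

TYPE_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"),
                "h2hINV": ("+", "+"), "t2tINV": ("-", "-")}


def make_sv(chrom, pos1, pos2, sv_type="DEL", chrom2=None, **kw):
    """Intrachromosomal SV from a span, or TRA when chrom2 differs."""
    if chrom2 is not None and chrom2 != chrom:
        return canonical_sv(chrom, pos1, "+", chrom2, pos2, "-", **kw)
    s1, s2 = TYPE_STRANDS[sv_type]
    return canonical_sv(chrom, pos1, s1, chrom, pos2, s2, **kw)


def random_sv_instance(rng, n_svs, chroms=("chr1", "chr2"), span=10_000):
    """Random intrachromosomal SV set for brute-force cluster oracles."""
    svs = []
    for i in range(n_svs):
        chrom = str(rng.choice(list(chroms)))
        a, b = sorted(rng.integers(0, span, size=2))
        if a == b:
            b += 1
        sv_type = str(rng.choice(["DEL", "DUP", "h2hINV", "t2tINV"]))
        svs.append(make_sv(chrom, int(a), int(b), sv_type, sv_id=f"r{i}"))
    return svs


@pytest.fixture(scope="session")
def tiny_genome():
    return Genome({"chr1": 5_000_000, "chr2": 4_000_000, "chr3": 3_000_000})


@pytest.fixture(scope="session")
def acceptance_cohort():
    """Noise-free 4-sample cohort with 2 planted CGRs (shared across tests)."""
    config = SimConfig(
        n_samples=4, n_truncal_snvs=50, n_shared_snvs=20, n_private_snvs=10,
        n_background_svs=8,
        cgr_specs=(
            CgrSpec(chromosomes=("chr15",), n_svs=6, style="chromothripsis",
                    amplified_gene="OncA", target_copies=8.0),
            CgrSpec(chromosomes=("chr7",), n_svs=5, style="bfb"),
        ),
        purity_per_sample=0.7, depth_mean=100.0, seed=17, n_controls=3)
    return simulate_cohort(config)
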