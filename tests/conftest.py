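import numpy as np
import pytest

from tadquant.locus import GenomicInterval
from tadquant.simulate import EnhancerSpec, SyntheticLocusConfig, generate_locus


def small_config(**overrides) -> SyntheticLocusConfig:
    """A 400-kb two-TAD locus small enough for per-test simulation."""
    chrom = "chrS"
    defaults = dict(
        chrom=chrom,
        locus_length=400_000,
        median_fragment_bp=800,
        cdom=GenomicInterval(chrom, 20_000, 180_000, "cdom"),
        cluster=GenomicInterval(chrom, 185_000, 195_000, "cluster"),
        tdom=GenomicInterval(chrom, 200_000, 360_000, "tdom"),
        next_tad=GenomicInterval(chrom, 360_000, 400_000, "next_tad"),
        enhancer_regions={
            "E_tel": EnhancerSpec(
                GenomicInterval(chrom, 260_000, 265_000, "E_tel"),
                {"proximal": 3.0, "distal": 1.5},
            ),
            "E_cen": EnhancerSpec(
                GenomicInterval(chrom, 80_000, 85_000, "E_cen"),
                {"proximal": 1.0, "distal": 3.0},
            ),
        },
        depth=50_000,
        chic_depth=120_000,
        chip_depth=60_000,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticLocusConfig(**defaults)


@pytest.fixture(scope="session")
def locus():
    return generate_locus(small_config(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
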