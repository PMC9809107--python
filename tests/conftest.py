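import numpy as np
import pytest

from pgtsr.genome import CytobandMap, GenomeModel, TranslocationSpec
from pgtsr.sim import build_derivatives


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    return GenomeModel.toy(seed=0)


@pytest.fixture(scope="session")
def toy_spec() -> TranslocationSpec:
    # q<->p exchange on a 2 x 5 Mb genome
    return TranslocationSpec(chrom_a="chr1", chrom_b="chr2",
                             bp_a=3_000_000, bp_b=1_200_000,
                             arm_a="q", arm_b="p")


@pytest.fixture(scope="session")
def toy_derivatives(toy_spec, toy_genome):
    return build_derivatives(toy_spec, toy_genome)


@pytest.fixture(scope="session")
def toy_cytobands(toy_genome) -> CytobandMap:
    return CytobandMap.toy(toy_genome.lengths)


@pytest.fixture(scope="session")
def qq_spec() -> TranslocationSpec:
    # q<->q exchange, as in the second pedigree
    return TranslocationSpec(chrom_a="chr1", chrom_b="chr2",
                             bp_a=3_000_000, bp_b=3_500_000,
                             arm_a="q", arm_b="q")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_genome() -> GenomeModel:
    """2 kb two-chromosome genome for exhaustive per-base scans."""
    return GenomeModel.toy(n_chromosomes=2, length=1_000, snp_spacing=100, seed=3)
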