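import numpy as np
import pytest

from mitoforge import (CircularSequence, MitogenomeSpec,
                       ReadProfile, generate_mitogenome, simulate_reads)
from mitoforge.seqs import FeatureKind
from mitoforge.synth import mutate_substitutions


def small_spec(seed: int = 0, cr_identity: float = 0.98) -> MitogenomeSpec:
    """A reduced mitogenome (~4.3 kb) with the same structural challenges
    as the default — duplicated CR with tandem-repeat tracts — for tests
    that do not need full scale."""
    P, T, R, C = (FeatureKind.PCG, FeatureKind.TRNA, FeatureKind.RRNA,
                  FeatureKind.CR)
    template = [
        ("tRNA-Phe", T, 70), ("12S rRNA", R, 400), ("tRNA-Val", T, 70),
        ("ND1", P, 600), ("COX1", P, 800), ("tRNA-Lys", T, 70),
        ("CYTB", P, 700), ("tRNA-Thr", T, 70), ("CR1", C, 0),
        ("tRNA-Glu", T, 70), ("CR2", C, 0),
    ]
    return MitogenomeSpec(total_length=4300, feature_template=template,
                          cr_length=500, cr_copy_identity=cr_identity,
                          tr_unit=40, tr_copies_cr1=4, tr_copies_cr2=4,
                          rng_seed=seed)


def diverged_reference(genome: CircularSequence, divergence: float = 0.02,
                       seed: int = 99) -> CircularSequence:
    rng = np.random.default_rng(seed)
    return CircularSequence(
        "reference",
        mutate_substitutions(genome.seq, round(divergence * genome.length), rng))


@pytest.fixture(scope="session")
def default_genome():
    """The full-scale default synthetic mitogenome and its annotation."""
    return generate_mitogenome(MitogenomeSpec(rng_seed=0))


@pytest.fixture(scope="session")
def small_genome():
    return generate_mitogenome(small_spec(seed=3))


@pytest.fixture(scope="session")
def small_reads(small_genome):
    genome, features = small_genome
    cr1 = next(a for a in features if a.name == "CR1")
    cr2 = next(a for a in features if a.name == "CR2")
    profile = ReadProfile(coverage=100.0, n_long=3, long_error=0.10,
                          long_length_mean=2200, long_length_sd=150,
                          long_span=(max(0, cr1.start - 200), cr2.end + 200))
    return simulate_reads(genome, profile, seed=41)
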