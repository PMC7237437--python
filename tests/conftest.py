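import numpy as np
import pytest

from smithrna.genome import AnnotationSet, CircularGenome, GenomeFeature, reannotate_urs


@pytest.fixture
def toy_genome():
    """100-bp circular genome with one gene at 11-90 (UR wraps the origin)."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    genome = CircularGenome("toy", seq)
    ann = AnnotationSet("toy", [GenomeFeature("pcg1", "PCG", 11, 90, "+")])
    return genome, reannotate_urs(ann, genome)


@pytest.fixture(scope="session")
def sim_system():
    """Deterministic 16-kb synthetic genome + annotation + 3 planted loci."""
    from smithrna.simulate import plant_loci, simulate_genome

    genome, annotation = simulate_genome(11)
    loci = plant_loci(genome, annotation, 3, seed=11)
    return genome, annotation, loci


@pytest.fixture(scope="session")
def conservation_system():
    """Six-region genome for diversity analyses (session-cached)."""
    from smithrna.simulate import simulate_conservation_system

    return simulate_conservation_system(3)
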