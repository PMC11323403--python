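import numpy as np
import pytest

from gcdrift import GenePlan, GenomeSpec, GcPeakSpec, generate_sequence, place_genes


@pytest.fixture(scope="session")
def small_annotated_genome():
    """A 400 kb chromosome with 20 genes and a GC peak at every TSS."""
    plan = GenePlan(n_genes=20, min_intergenic_gap=4000)
    genes, scores = place_genes(400_000, plan, seed=11)
    spec = GenomeSpec(length=400_000, background_gc=0.41, seed=11)
    genome = generate_sequence(
        spec, [(g.tss, GcPeakSpec(amplitude=0.25, sigma=400)) for g in genes]
    )
    return genome, genes, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
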