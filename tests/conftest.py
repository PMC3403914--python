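import numpy as np
import pytest

from gisland import synthetic as syn


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic replicon exercising every planted feature kind."""
    spec = syn.SyntheticSpec(
        length=120_000,
        islands=[syn.IslandSpec(n_orfs=12, gc=0.37, at_fraction=0.65,
                                terminal_repeat=15)],
        duplications=[syn.DupSpec(length=1200, n_edits=3, gap=0,
                                  at_fraction=0.85)],
        primer_pairs=[syn.PrimerSpec("AGCATCGGTCAGCTGAATCT",
                                     "GGTTAGAGCGTGGTGCATTT", 565,
                                     at_fraction=0.3)],
        n_cytochromes=3,
        n_decoys=3,
        n_reference_proteomes=3,
        mean_gene_aa=220,
        sd_gene_aa=50,
    )
    return syn.generate(spec, seed=11)


@pytest.fixture(scope="session")
def island_bundle():
    """Study-scale conditions: 300 kb host, one 30-ORF island at 37% GC."""
    spec = syn.SyntheticSpec(
        length=300_000,
        islands=[syn.IslandSpec(n_orfs=30, gc=0.37, at_fraction=0.6)],
    )
    return syn.generate(spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def random_protein(rng, n):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(np.array(list(aas))[rng.choice(20, size=n)])
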