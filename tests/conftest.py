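import numpy as np
import pytest

from supmap.genome import SparseGenome
from supmap.mapping import MappingParams
from supmap.pipeline import run_e2e
from supmap.screen import ScreenConfig, simulate_screen, tiny_config
from supmap import sim


@pytest.fixture(scope="session")
def tiny_bundle():
    """Desk-scale recessive screen (2 chromosomes x 2 Mb) used across modules."""
    return simulate_screen(tiny_config(seed=5))


def tiny_mapping_params() -> MappingParams:
    """Window geometry scaled to the 2 Mb fixture chromosomes."""
    return MappingParams(window_size=200_000, min_markers_per_window=2,
                         min_interval_span=150_000)


@pytest.fixture(scope="session")
def full_e2e():
    """One full-scale recessive screen through the whole pipeline."""
    return run_e2e(ScreenConfig(seed=42))


@pytest.fixture
def small_map():
    """One 1 Mb chromosome with 10 markers."""
    return sim.build_marker_map({"I": 1_000_000}, 10.0, np.random.default_rng(1))


def het_individual(marker_map, variant, rng=None):
    """A/B heterozygote carrying ``variant`` on the A haplotype."""
    ind = sim.make_founder(marker_map, False)
    haps = {}
    for name, cm in marker_map.chroms.items():
        h0, _ = ind.haplotypes[name]
        vs = frozenset({variant}) if variant is not None and variant.chrom == name \
            else frozenset()
        haps[name] = (sim.Haplotype(np.zeros(cm.n_markers, bool), vs),
                      sim.Haplotype(np.ones(cm.n_markers, bool), frozenset()))
    return sim.Individual(haps)


def dosed_individual(marker_map, variant, dose):
    """Homozygous-A individual carrying ``variant`` on ``dose`` haplotypes."""
    haps = {}
    for name, cm in marker_map.chroms.items():
        vs = [frozenset(), frozenset()]
        if variant.chrom == name:
            for i in range(dose):
                vs[i] = frozenset({variant})
        haps[name] = (sim.Haplotype(np.zeros(cm.n_markers, bool), vs[0]),
                      sim.Haplotype(np.zeros(cm.n_markers, bool), vs[1]))
    return sim.Individual(haps)


def toy_variant(chrom="I", pos=500_001, role="causal"):
    return sim.EMSVariant(chrom, pos, "G", "A", role, "missense")


@pytest.fixture
def toy_gene_setup():
    """A sparse genome with one gene and a low-density marker map."""
    genome = SparseGenome({"I": 200_000}, seed=7)
    rng = np.random.default_rng(7)
    gene = sim.make_gene("g1", "I", 50_000, genome, rng, strand="+")
    marker_map = sim.build_marker_map({"I": 200_000}, 50.0, rng, genome=genome)
    return genome, gene, marker_map, rng
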