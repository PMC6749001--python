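import warnings

import numpy as np
import pytest

from lineagesv import simulate as sim
from lineagesv.pipeline import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore", message=".*anchor pairs.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231105)


@pytest.fixture(scope="session")
def small_world():
    """A compact substitution-free simulation shared by lineage/asmqc tests.

    One 400 kb chromosome with 30% planted repeats; a handful of events on
    each branch so every inference stage has work to do.
    """
    ancestor = sim.generate_ancestral_genome(1, 400_000, repeat_fraction=0.3, seed=101)
    specs = [
        sim.BranchSpec("ape_ancestor", n_del=8, n_ins=4),
        sim.BranchSpec("macaque", n_del=5, n_ins=3),
        sim.BranchSpec("marmoset"),
    ] + [sim.BranchSpec(t, n_del=3, n_ins=2) for t in sim.APE_TIPS]
    genomes, truth = sim.evolve_genomes(ancestor, specs, seed=102)
    return ancestor, genomes, truth


@pytest.fixture(scope="session")
def default_report_nosubst():
    """Full default pipeline run with the substitution-free study conditions."""
    return run_pipeline(PipelineConfig(seed=1, subst_rate=0.0))


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down configuration for fast orchestration tests."""
    return PipelineConfig(
        seed=7, n_chrom=1, chrom_length=150_000, repeat_fraction=0.3,
        event_scale=0.15, subst_rate=0.0, n_gaps=3, n_enhancers=200,
        n_perm=60, n_iter=150, n_trait_genes=12, n_private_human_svs=2,
        subtelo_margin=20_000, window=50_000,
    )
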