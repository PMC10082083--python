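"""Shared fixtures: simulated datasets at the scales the checks need.

Session-scoped so the expensive simulations run once per session.  All
seeds are fixed constants; the generator is deterministic given its config.
"""

import pytest

from pinemeth.config import PipelineConfig, SimConfig
from pinemeth import pipeline
from pinemeth.simulate import simulate_dataset


@pytest.fixture(scope="session")
def pcfg() -> PipelineConfig:
    return PipelineConfig()


def tiny_config(**overrides) -> SimConfig:
    """A seconds-scale dataset with every planted feature present."""
    base = dict(
        seed=0, n_chromosomes=1, chrom_length_bp=500_000, n_genes=15,
        n_marker_genes=2, n_planted_age_dmrs={("CHG", "hyper"): 20},
        n_replicate_variable_bins=10, lambda_genome_bp=20_000,
    )
    base.update(overrides)
    return SimConfig(**base)


#: Study-design scale: 4 ages x 2 replicates at ~20x on a 2x1-Mb genome,
#: 200 age-linear CHG bins (0.4 -> 0.7), 100 replicate-variable CG bins,
#: 10 age-marker genes.
MAIN_CONFIG = SimConfig(
    seed=0,
    n_chromosomes=2,
    chrom_length_bp=1_000_000,
    n_genes=120,
    n_marker_genes=10,
    n_planted_age_dmrs={("CHG", "hyper"): 200},
    n_replicate_variable_bins=100,
    te_fraction=0.45,
    lambda_genome_bp=150_000,
)

#: Expression-linkage scale: one 2-Mb chromosome dense with short genes so
#: all five TPM groups are populated.
EXPR_CONFIG = SimConfig(
    seed=0, n_chromosomes=1, chrom_length_bp=2_000_000, n_genes=250,
    intron_frac_gt_5kb=0.02, intron_frac_gt_20kb=0.0, n_introns_range=(0, 4),
    te_fraction=0.05, lambda_genome_bp=5_000,
)

#: Null scale: no planted signal of any kind; ages share identical states.
NULL_CONFIG = SimConfig(
    seed=0, n_chromosomes=1, chrom_length_bp=1_000_000, n_genes=40,
    n_marker_genes=0, te_fraction=0.40, lambda_genome_bp=5_000,
)


@pytest.fixture(scope="session")
def tiny_ds():
    return simulate_dataset(tiny_config())


@pytest.fixture(scope="session")
def main_ds():
    return simulate_dataset(MAIN_CONFIG)


@pytest.fixture(scope="session")
def main_dmr(main_ds, pcfg):
    return pipeline.dmr_stage(main_ds, pcfg)


@pytest.fixture(scope="session")
def main_trend(main_ds, main_dmr, pcfg):
    return pipeline.trend_stage(main_dmr, main_ds.sheet, main_ds.annotation,
                                pcfg, seed=0)


@pytest.fixture(scope="session")
def expr_ds():
    return simulate_dataset(EXPR_CONFIG)


@pytest.fixture(scope="session")
def null_ds():
    return simulate_dataset(NULL_CONFIG)
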