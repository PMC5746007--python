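import pytest

from tetscan import simulate


@pytest.fixture(scope="session")
def small_genome():
    return simulate.make_genome(
        n_genes=200,
        chromosome_spec=[("2L", 5_000_000), ("2R", 5_000_000), ("3L", 4_000_000)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_design():
    return simulate.StrainDesign(
        strains=[
            ("ctrl", None, None, "none"),
            ("insA", "2L", 2_500_000, "het"),
            ("insB", "3L", 2_000_000, "het"),
        ],
        stages=("larva",),
        replicates=3,
    )


@pytest.fixture(scope="session")
def small_experiment(small_genome, small_design):
    """A seeded 3-strain, 1-stage experiment with 4 shared-core DE genes."""
    effects = simulate.EffectModel(shared_core=(4, 1.0), seed=5)
    truth = simulate.simulate_effects(small_genome, small_design, effects)
    return simulate.simulate_intensities(
        small_genome, small_design, truth,
        probes_per_gene=2, n_negative_controls=100, seed=7,
    )
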