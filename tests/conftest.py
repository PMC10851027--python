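"""Shared fixtures: genome configs, neutral envelopes and replicate-set runs.

The heavier simulation fixtures are session-scoped and shared between the
power-property tests and the acceptance tests; all seeds are fixed so the
suite is deterministic. Problem sizes are desk-scale (hundreds of markers,
tens of replicate sets) while keeping the study conditions themselves
(N = 1000 diploids, selection coefficients, sampling generations) intact.
"""

import numpy as np
import pytest
from hypothesis import settings

import dmimap as dm

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

S_STRONG_TWOWAY = 1.0 - np.sqrt(0.2)  # 1-(1-s)^2 = 0.8 per incompatibility pair


@pytest.fixture(scope="session")
def tiny_genome():
    """Few markers; for engine-level checks where locus count is irrelevant."""
    return dm.GenomeConfig(markers_per_chromosome=10)


@pytest.fixture(scope="session")
def two_locus_genome():
    """Desk-scale mapping genome: 500 markers per 20.8 Mb chromosome."""
    return dm.GenomeConfig(markers_per_chromosome=500)


@pytest.fixture(scope="session")
def two_locus_envelope(two_locus_genome):
    """Neutral envelope for the single-pair architecture at generations 10/100."""
    dmi = dm.place_two_locus_dmi(two_locus_genome, s=0.0)
    return dm.build_envelope(two_locus_genome, [dmi], n_individuals=1000,
                             sample_generations=(10, 100), n_neutral_sims=150,
                             seed=901)


@pytest.fixture(scope="session")
def oneway_weak_gen10_run(two_locus_genome, two_locus_envelope):
    """Weak one-way DMI (s=0.05) detected at generation 10: 40 sets x 10 pops."""
    dmi = dm.place_two_locus_dmi(two_locus_genome, s=0.05, interaction="one_way")
    exp = dm.ExperimentConfig(n_replicate_pops=10, sample_generations=(10,),
                              n_replicate_sets=40, rng_seed=101)
    return dm.run_two_locus_experiment(two_locus_genome, dmi, dm.FitnessModel(),
                                       exp, envelope=two_locus_envelope)


@pytest.fixture(scope="session")
def twoway_recessive_run(two_locus_genome, two_locus_envelope):
    """Strong recessive x recessive two-way DMI: 15 sets x 10 pops, gens 10/100."""
    dmi = dm.place_two_locus_dmi(two_locus_genome, s=S_STRONG_TWOWAY,
                                 interaction="two_way",
                                 dominance_a="recessive", dominance_b="recessive")
    exp = dm.ExperimentConfig(n_replicate_pops=10, sample_generations=(10, 100),
                              n_replicate_sets=15, rng_seed=102)
    return dm.run_two_locus_experiment(two_locus_genome, dmi, dm.FitnessModel(),
                                       exp, envelope=two_locus_envelope)


@pytest.fixture(scope="session")
def twoway_dominant_run(two_locus_genome, two_locus_envelope):
    """Strong dominant x dominant two-way DMI: 15 sets x 10 pops, gens 10/100."""
    dmi = dm.place_two_locus_dmi(two_locus_genome, s=S_STRONG_TWOWAY,
                                 interaction="two_way")
    exp = dm.ExperimentConfig(n_replicate_pops=10, sample_generations=(10, 100),
                              n_replicate_sets=15, rng_seed=103)
    return dm.run_two_locus_experiment(two_locus_genome, dmi, dm.FitnessModel(),
                                       exp, envelope=two_locus_envelope)


@pytest.fixture(scope="session")
def tradeoff_genome():
    return dm.GenomeConfig(markers_per_chromosome=250)


@pytest.fixture(scope="session")
def oneway_strong_grid(tradeoff_genome):
    """Strong one-way DMI followed to generation 500 (accuracy/precision trade-off)."""
    dmi = dm.place_two_locus_dmi(tradeoff_genome, s=0.8, interaction="one_way")
    env = dm.build_envelope(tradeoff_genome, [dmi], n_individuals=1000,
                            sample_generations=(20, 100, 500),
                            n_neutral_sims=100, seed=902)
    exp = dm.ExperimentConfig(n_replicate_pops=10, sample_generations=(20, 100, 500),
                              n_replicate_sets=10, rng_seed=104)
    return dm.run_two_locus_experiment(tradeoff_genome, dmi, dm.FitnessModel(),
                                       exp, envelope=env)


@pytest.fixture(scope="session")
def multilocus_setup():
    """10 random one-way DMI pairs (additive s=0.02), 1000 markers/chromosome."""
    genome = dm.GenomeConfig(markers_per_chromosome=1000)
    rng = np.random.default_rng(903)
    dmis = dm.place_multi_locus_dmis(genome, n_pairs=10, s=0.02, rng=rng)
    return genome, dmis


@pytest.fixture(scope="session")
def multilocus_run(multilocus_setup):
    """Multi-locus block mapping: 15 sets x 5 pops at generation 100."""
    genome, dmis = multilocus_setup
    env = dm.build_envelope(genome, dmis, n_individuals=1000,
                            sample_generations=(100,), n_neutral_sims=150,
                            seed=904)
    exp = dm.ExperimentConfig(n_replicate_pops=5, sample_generations=(100,),
                              n_replicate_sets=15, rng_seed=105)
    model = dm.FitnessModel(composition="additive")
    return dm.run_multi_locus_experiment(genome, dmis, model, exp, envelope=env)


@pytest.fixture(scope="session")
def fresh_neutral_pops(two_locus_genome):
    """20 neutral populations not used to build the envelope (calibration)."""
    dmi = dm.place_two_locus_dmi(two_locus_genome, s=0.0)
    loci = dm.build_locus_table(two_locus_genome, [dmi])
    freqs = {10: [], 100: []}
    for i in range(20):
        traj = dm.run_replicate(two_locus_genome, [dmi], dm.FitnessModel(), 1000,
                                (10, 100), np.random.SeedSequence(905, spawn_key=(i,)),
                                loci=loci)
        freqs[10].append(traj.at_generation(10))
        freqs[100].append(traj.at_generation(100))
    return {g: np.vstack(v) for g, v in freqs.items()}
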