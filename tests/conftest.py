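import numpy as np
import pytest

import hoofbeats as hb


@pytest.fixture(scope="session")
def scheme():
    return hb.build_bin_scheme()


@pytest.fixture(scope="session")
def small_population():
    """6 individuals x 3 gaits at 30 s: cheap but structurally realistic."""
    pop = hb.PopulationSpec(n_individuals=6, individual_tempo_sd=0.06, seed=11)
    return hb.simulate_population(pop, hb.default_specs(duration_s=30.0))


@pytest.fixture(scope="session")
def zero_jitter_specs():
    from dataclasses import replace

    return [replace(s, jitter_cv=0.0) for s in hb.default_specs(duration_s=30.0)]


@pytest.fixture(scope="session")
def tiny_embedding():
    """Jittered 3-gait embedding small enough for fast classifier tests."""
    from hoofbeats import pipeline

    pop = hb.PopulationSpec(n_individuals=3, individual_tempo_sd=0.06, seed=5)
    recs = hb.simulate_population(pop, hb.default_specs(duration_s=30.0))
    triplets = pipeline.build_triplet_table(recs)
    return hb.embed_triplets(triplets, n_neighbors=10, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
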