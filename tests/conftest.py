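import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_topology():
    """Four-layer toy network with a recurrent cleanup loop."""
    from triread.netcore import NetworkTopology
    return NetworkTopology(
        layers=(("inp", 3), ("hid", 4), ("out", 3), ("clean", 2)),
        connections=(("inp", "hid"), ("hid", "out"), ("out", "clean"),
                     ("clean", "out")))


@pytest.fixture(scope="session")
def small_lexicon():
    """50-word quasi-regular lexicon with homophones and deviants."""
    from triread.lexicon import LexiconParams, generate_lexicon
    params = LexiconParams(n_words=50, semantic_dim=100,
                           n_active_range=(4, 10),
                           n_homophone_families=3,
                           family_size_range=(3, 5))
    return generate_lexicon(params, seed=7)


@pytest.fixture(scope="session")
def small_topology(small_lexicon):
    from triread.netcore import NetworkTopology
    return NetworkTopology.triangle(
        small_lexicon.spec, hidden_op=60, hidden_os=60, hidden_ps=40,
        hidden_sp=40, attractor=10)


@pytest.fixture(scope="session")
def small_compiled(small_lexicon):
    from triread.training import CompiledLexicon
    return CompiledLexicon(small_lexicon)


@pytest.fixture(scope="session")
def oral_weights(small_lexicon, small_topology, small_compiled):
    """Oral-phase endpoint on the 50-word lexicon (30k trials)."""
    from triread.netcore import init_network
    from triread.training import RegimenSpec, run_oral_phase
    regimen = RegimenSpec("OP-focused", 0.75, 0.25, oral_trials=30_000,
                          reading_trials=0, seed=0)
    init = init_network(small_topology, 0.1, seed=0)
    weights, log = run_oral_phase(init, small_compiled, regimen,
                                  learning_rate=0.02, log_interval=30_000)
    return weights, log


@pytest.fixture(scope="session")
def reading_weights(oral_weights, small_compiled):
    """OP-focused reading endpoint on top of the shared oral weights."""
    from triread.training import RegimenSpec, run_reading_phase
    regimen = RegimenSpec("OP-focused", 0.75, 0.25, oral_trials=30_000,
                          reading_trials=15_000, seed=0)
    weights, log = run_reading_phase(oral_weights[0], small_compiled,
                                     regimen, learning_rate=0.02,
                                     log_interval=15_000)
    return weights, log


def random_toy_network(rng, dtype=np.float64):
    """Random small recurrent topology + weights for gradient checks."""
    from triread.study import random_recurrent_network
    return random_recurrent_network(rng, dtype=dtype)
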