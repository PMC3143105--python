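import pytest

from pr19scan import classify, synthetic


@pytest.fixture(scope="session")
def small_library():
    """A compact noise-free simulated library (both configurations)."""
    config = synthetic.SimulationConfig(
        seed=101, reference_length=30000, n_events_a=25, n_events_b=25,
        antisense_fraction=0.4,
    )
    return synthetic.simulate_library(config)


@pytest.fixture(scope="session")
def small_classified(small_library):
    classified, summary = classify.classify_library(
        small_library.alignments, small_library.references
    )
    return classified, summary


@pytest.fixture(scope="session")
def truth_classes(small_library):
    return dict(
        zip(small_library.truth.read_id, small_library.truth.true_class)
    )
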