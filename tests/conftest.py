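import pytest

from pmforge.pipeline import assemble, evaluate_against_truth
from pmforge.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """The default simulated study: 3 chromosomes, ~60 scaffolds, 2 chimeras."""
    return simulate_all(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_assembly(default_bundle):
    b = default_bundle
    lengths = {sid: s.length for sid, s in b.scaffolds.items()}
    return assemble(lengths, b.alignments, b.genetic_map, b.pairs, b.libraries)


@pytest.fixture(scope="session")
def default_recovery(default_bundle, default_assembly):
    return evaluate_against_truth(default_assembly, default_bundle.truth)
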