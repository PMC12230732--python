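import numpy as np
import pytest

from sigsearch import (
    BitIndex,
    GeneSet,
    LibrarySpec,
    QuerySpec,
    build_bit_index,
    build_universe,
    generate_library,
    generate_queries,
    pair_signatures,
)


@pytest.fixture
def tiny_pairs():
    """Three handcrafted signature pairs over a small explicit universe."""
    sets = [
        GeneSet("B000_HCC515_6H_A01_drugA_10 uM up", frozenset({"TP53", "BAX", "CDKN1A"})),
        GeneSet("B000_HCC515_6H_A01_drugA_10 uM down", frozenset({"MYC", "CCND1"})),
        GeneSet("B001_MCF7_24H_B02_drugB_1 uM up", frozenset({"EGFR", "KRAS"})),
        GeneSet("B001_MCF7_24H_B02_drugB_1 uM down", frozenset({"TP53", "GAPDH"})),
        GeneSet("B002_PC3_6H_C03_drugC_10 uM up", frozenset({"ACTB", "BAX"})),
        GeneSet("B002_PC3_6H_C03_drugC_10 uM down", frozenset({"VIM", "FN1"})),
    ]
    pairs, unpaired = pair_signatures(sets)
    assert not unpaired
    return pairs


@pytest.fixture
def tiny_index(tiny_pairs) -> BitIndex:
    return build_bit_index(tiny_pairs, build_universe(tiny_pairs))


@pytest.fixture(scope="session")
def small_spec() -> LibrarySpec:
    """A small but structured library: 20 perturbations x 12 contexts."""
    return LibrarySpec(
        universe_size=600,
        n_perturbations=20,
        contexts_per_perturbation=12,
        effect_size=40,
        signature_set_size=100,
        signal_fraction=0.6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_library(small_spec):
    return generate_library(small_spec)


@pytest.fixture(scope="session")
def small_index(small_library) -> BitIndex:
    pairs, _ = small_library
    return build_bit_index(pairs, build_universe(pairs))


@pytest.fixture(scope="session")
def small_queries(small_library):
    _, truth = small_library
    rng = np.random.default_rng(11)
    targets = [str(t) for t in rng.choice(sorted(truth.effects), size=2, replace=False)]
    out = []
    for i, t in enumerate(targets):
        out += generate_queries(
            QuerySpec(target_perturbation=t, query_size=100, n_queries=6, seed=50 + i),
            truth,
        )
    return out
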