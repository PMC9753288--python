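import pytest

from herbscreen.compound_io import CompoundLibrary, CompoundRecord
from herbscreen.synthetic import GeneratorConfig


@pytest.fixture
def tiny_library() -> CompoundLibrary:
    """Three hand-picked molecules with varied tags."""
    return CompoundLibrary([
        CompoundRecord("c1", "CCO", name="ethanol", tags=frozenset({"tumor"})),
        CompoundRecord("c2", "c1ccccc1", name="benzene",
                       tags=frozenset({"inflammation"})),
        CompoundRecord("c3", "CC(=O)Oc1ccccc1C(=O)O", name="aspirin",
                       tags=frozenset({"tumor", "inflammation"})),
    ])


@pytest.fixture
def small_config() -> GeneratorConfig:
    """Generator conditions scaled down for fast unit tests."""
    return GeneratorConfig(n_library=60, n_tagged=20, seed=11)


@pytest.fixture(scope="session")
def modeling_assets():
    """A small planted-signal modeling dataset with aligned descriptors.

    Session-scoped: several QSAR tests share it read-only.
    """
    from herbscreen.curation import build_dataset
    from herbscreen.descriptors import featurize_library
    from herbscreen.synthetic import generate_bioactivity, generate_library, \
        modeling_config

    conf = modeling_config(n=160, seed=5)
    lib, _ = generate_library(conf)
    records, truth = generate_bioactivity(lib, conf)
    dataset = build_dataset(records, lib)
    features = featurize_library(lib)
    return {"config": conf, "library": lib, "dataset": dataset,
            "features": features, "truth": truth}
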