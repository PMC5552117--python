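import pytest

from allelichrom import io, synthetic


@pytest.fixture(scope="session")
def default_generator():
    return synthetic.GeneratorConfig(n_genes=3000, seed=5)


@pytest.fixture(scope="session")
def dataset(default_generator):
    """One medium default-config dataset shared across test modules."""
    annotation, truth, counts = synthetic.generate_dataset(default_generator)
    return {"annotation": annotation, "truth": truth, "counts": counts,
            "config": default_generator}


@pytest.fixture(scope="session")
def run_config(default_generator):
    cfg = io.RunConfig()
    cfg.generator = default_generator
    return cfg
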