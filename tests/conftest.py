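import numpy as np
import pytest

import evopotts as ep


@pytest.fixture(scope="session")
def bias():
    return ep.NucleotideBias.default()


@pytest.fixture(scope="session")
def mm_l1(bias):
    """Mutation model for a 1-residue gene at moderate load."""
    return ep.build_kernels(bias, 0.3, 1)


@pytest.fixture(scope="session")
def mm_l2(bias):
    return ep.build_kernels(bias, 0.5, 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_potts(L: int, seed: int, coupling_scale: float = 1.0) -> ep.PottsModel:
    r = np.random.default_rng(seed)
    P = L * (L - 1) // 2
    return ep.PottsModel(
        r.normal(0, 1, (L, 20)), r.normal(0, coupling_scale, (P, 20, 20))
    )


@pytest.fixture(scope="session")
def fixture_pipeline():
    """The default planted fixture run end-to-end once per session.

    Simulation plus the full 300-step fit take a few minutes; every recovery
    assertion shares this single run (pinned seed 42).
    """
    truth, dataset, model, manifest = ep.default_fixture(seed=42)
    data = {
        r: ep.empirical_frequencies(dataset.rounds[r])
        for r in dataset.sequenced_rounds
    }
    landscape, fit = ep.infer_landscape(data, model, truth.wildtype)
    return {
        "truth": truth,
        "dataset": dataset,
        "model": model,
        "manifest": manifest,
        "data": data,
        "landscape": landscape,
        "fit": fit,
    }
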