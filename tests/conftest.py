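import numpy as np
import pytest

from pccsort.simulate import (
    BindingModel,
    ErrorModel,
    apply_classification_error,
    sample_true_occupancy,
)
from pccsort.sorting import count_missing_per_particle, formula_distribution
from pccsort.symmetry import (
    build_c2_action,
    build_c3_action,
    build_d3_action,
    build_trivial_action,
)


@pytest.fixture(scope="session")
def d3():
    return build_d3_action()


@pytest.fixture(scope="session", params=["D3", "C3", "C2", "trivial"])
def any_action(request):
    return {
        "D3": build_d3_action,
        "C3": build_c3_action,
        "C2": build_c2_action,
        "trivial": build_trivial_action,
    }[request.param]()


def run_pipeline(p: float, n: int, seed: int, eps_fn: float = 0.0, eps_fp: float = 0.0):
    """simulate -> sort, returning (truth, records, distribution)."""
    truth = sample_true_occupancy(BindingModel.independent(p), n, seed=seed)
    records = apply_classification_error(
        truth, ErrorModel(eps_fn=eps_fn, eps_fp=eps_fp), seed=seed + 10_000
    )
    dist = formula_distribution(count_missing_per_particle(records))
    return truth, records, dist


@pytest.fixture(scope="session")
def pipeline():
    return run_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
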