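"""Shared fixtures: toy models, condition pairs, and reusable sample sets.

Sampling fixtures are session-scoped so the Markov chains run once; all
randomness is seeded, so the suite is deterministic end to end.
"""

import numpy as np
import pytest

from halogem.fba_engine import apply_condition
from halogem.flux_sampling import hit_and_run_sample
from halogem.network_core import GPRRule, Metabolite, MetabolicModel, Reaction
from halogem.synthetic_data import (
    ToySpec,
    make_condition_pair,
    make_ectoine_cycles_model,
    make_toy_core_model,
)


@pytest.fixture(scope="session")
def toy_core():
    """Core 3-compartment toy and its generator-side truth."""
    return make_toy_core_model()


@pytest.fixture(scope="session")
def condition_pair():
    return make_condition_pair()  # growth pinned at 1.0, ATPM 7.6


@pytest.fixture(scope="session")
def sampled_pair(toy_core, condition_pair):
    """2000-point hit-and-run samples of the low/high salinity conditions."""
    model, _ = toy_core
    low = apply_condition(model, condition_pair.low)
    high = apply_condition(model, condition_pair.high)
    s_low = hit_and_run_sample(low, 2000, seed=101, condition="low_salinity")
    s_high = hit_and_run_sample(high, 2000, seed=202, condition="high_salinity")
    return s_low, s_high


@pytest.fixture(scope="session")
def cycles_model():
    return make_ectoine_cycles_model(4)


@pytest.fixture(scope="session")
def cycles_sample(cycles_model):
    return hit_and_run_sample(cycles_model, 1500, seed=77, condition="cycles")


def small_box_model(width: float = 10.0) -> MetabolicModel:
    """One metabolite, uptake/secretion pair: a 1-D flux interval [0, width]."""
    return MetabolicModel(
        metabolites=[Metabolite(id="a[c]")],
        reactions=[
            Reaction("EX_in", "", {"a[c]": -1.0}, -width, 0.0, "", GPRRule(), "exchange"),
            Reaction("EX_out", "", {"a[c]": -1.0}, 0.0, width, "", GPRRule(), "exchange"),
        ],
        genes=[],
        objective_id="EX_out",
        id="box1d",
    )


def simplex_model() -> MetabolicModel:
    """Two consumers fed by a supply capped at 1: the simplex v1 + v2 <= 1."""
    return MetabolicModel(
        metabolites=[Metabolite(id="a[c]")],
        reactions=[
            Reaction("SUP", "", {"a[c]": 1.0}, 0.0, 1.0, "", GPRRule(), "exchange"),
            Reaction("R1", "", {"a[c]": -1.0}, 0.0, 1000.0, "", GPRRule(), "metabolic"),
            Reaction("R2", "", {"a[c]": -1.0}, 0.0, 1000.0, "", GPRRule(), "metabolic"),
        ],
        genes=[],
        objective_id="R1",
        id="simplex2d",
    )


@pytest.fixture
def box1d():
    return small_box_model()


@pytest.fixture
def simplex2d():
    return simplex_model()


def assert_close(a, b, atol=1e-9, msg=""):
    assert np.isclose(a, b, atol=atol, rtol=0), msg or f"{a} != {b} (atol {atol})"
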