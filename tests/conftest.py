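"""Shared fixtures: small gating models and rendered traces."""

from __future__ import annotations

import numpy as np
import pytest

from singlechan import Condition
from singlechan.gating import (Exponential, GatingModel, GatingState, Pareto,
                               make_regime)


def two_state_model(tau_open=4e-3, tau_closed=1e-3, **kwargs) -> GatingModel:
    defaults = dict(noise_sigma=0.0, filter_cutoff=None)
    defaults.update(kwargs)
    return GatingModel(
        states=(GatingState("O", True, Exponential(tau_open)),
                GatingState("C", False, Exponential(tau_closed))),
        transition_probs=np.array([[0.0, 1.0], [1.0, 0.0]]),
        **defaults,
    )


def pareto_closed_model(alpha=1.5, t_min=1e-4, t_max=None, **kwargs) -> GatingModel:
    defaults = dict(noise_sigma=0.0, filter_cutoff=None)
    defaults.update(kwargs)
    return GatingModel(
        states=(GatingState("O", True, Exponential(4e-3)),
                GatingState("C", False, Pareto(alpha, t_min, t_max))),
        transition_probs=np.array([[0.0, 1.0], [1.0, 0.0]]),
        **defaults,
    )


def five_state_model(**kwargs) -> GatingModel:
    """O1,O2 + C1,C2,C3 with deliberately asymmetric transition rows."""
    defaults = dict(noise_sigma=0.0, filter_cutoff=None)
    defaults.update(kwargs)
    states = (
        GatingState("O1", True, Exponential(2e-3)),
        GatingState("O2", True, Exponential(9e-3)),
        GatingState("C1", False, Exponential(0.7e-3)),
        GatingState("C2", False, Exponential(5e-3)),
        GatingState("C3", False, Exponential(25e-3)),
    )
    P = np.array([
        [0.0, 0.0, 0.6, 0.3, 0.1],
        [0.0, 0.0, 0.2, 0.5, 0.3],
        [0.7, 0.3, 0.0, 0.0, 0.0],
        [0.4, 0.6, 0.0, 0.0, 0.0],
        [0.5, 0.5, 0.0, 0.0, 0.0],
    ])
    return GatingModel(states=states, transition_probs=P, **defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def control_model() -> GatingModel:
    return make_regime("control")
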