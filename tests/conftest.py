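"""Shared fixtures: small plans and motion models for fast unit tests."""

import numpy as np
import pytest

from tomolot import DeliveryPlan, LeafMotionModel


def make_small_plan(
    lots_by_projection, t_proj=348.0, leaves=(27, 39, 47), jaw=2.5, plan_id="small", x=None
) -> DeliveryPlan:
    """Plan with the given per-projection LOT pattern on a few leaves."""
    lots = np.asarray(lots_by_projection, dtype=float)
    matrix = np.zeros((64, lots.size))
    for leaf in leaves:
        matrix[leaf - 1] = lots
    return DeliveryPlan(
        plan_id=plan_id,
        n_projections=lots.size,
        t_proj=t_proj,
        jaw_opening=jaw,
        planned_lot=matrix,
        lot_fraction_x=x,
    )


@pytest.fixture
def small_plan():
    """Eight projections at 50% LOT on the three chamber leaves."""
    return make_small_plan([174.0] * 8, x=0.5)


@pytest.fixture
def quiet_model():
    """Default physics with every stochastic term switched off."""
    return LeafMotionModel(
        mv_noise_sd=0.0,
        jitter_sd=0.0,
        arcing_rate=0.0,
        charge_noise_rel=0.0,
        optical_resolution=0.0,
    )


@pytest.fixture
def exact_model():
    """Noiseless *and* analytically exact: linear fluence ramp, equal
    transition durations, sensors spanning the full transition.  Under this
    model the MV, optical and charge routes agree to float precision."""
    return LeafMotionModel(
        open_transition=20.0,
        close_transition=20.0,
        lot_shift=0.0,
        fluence_ramp="linear",
        sensor_open_fraction=1.0,
        sensor_close_fraction=1.0,
        mv_noise_sd=0.0,
        jitter_sd=0.0,
        arcing_rate=0.0,
        charge_noise_rel=0.0,
        optical_resolution=0.0,
    )
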