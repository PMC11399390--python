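"""Shared fixtures: arenas and a medium synthetic session reused across tests."""

import numpy as np
import pytest

from egospace import (CellSpec, compute_covariates, l_arena,
                      make_synthetic_session, simulate_trajectory,
                      square_arena)


@pytest.fixture(scope="session")
def sq_arena():
    return square_arena()


@pytest.fixture(scope="session")
def L_arena():
    return l_arena()


@pytest.fixture(scope="session")
def sq_trajectory(sq_arena):
    """20-minute foraging path in the square (seed fixed for the suite)."""
    return simulate_trajectory(sq_arena, 1200.0, seed=11)


@pytest.fixture(scope="session")
def roster():
    return {
        "bearing": CellSpec("center_bearing", peak_rate=12.0, baseline_rate=0.5,
                            pref_angle=90.0, kappa=3.0),
        "hd": CellSpec("hd_unidirectional", peak_rate=15.0, baseline_rate=0.5,
                       pref_angle=210.0, kappa=4.0),
        "noise": CellSpec("noise", peak_rate=3.0),
    }


@pytest.fixture(scope="session")
def sq_session(sq_arena, sq_trajectory, roster):
    """Synthetic square session with a bearing cell, an HD cell and a noise cell."""
    return make_synthetic_session(sq_arena, 1200.0, roster, seed=11,
                                  trajectory=sq_trajectory, label="Square1")


@pytest.fixture(scope="session")
def sq_covariates(sq_session):
    return sq_session.covariates
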