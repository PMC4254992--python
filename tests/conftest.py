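"""Shared fixtures: desk-scale simulation campaigns reused across tests.

Campaigns use mean recruitment R_mean = 4e4 (1% of the full-scale study's
4e6): proportional indices and the power-law slope are invariant to the
recruitment scale, while the intercept shifts by exactly ln(scale), so
desk-scale campaigns reproduce full-scale statistical behaviour at a
fraction of the cost.  Fixtures are session-scoped because a campaign of a
few hundred ten-year simulations takes on the order of a minute.
"""

from __future__ import annotations

import numpy as np
import pytest

from krillsim import RecruitmentParams, SimulationConfig, run_campaign

DESK_R_MEAN = 4e4
DESK_SCALE = DESK_R_MEAN / 4e6  # relative to the full-scale study


def desk_config(**recruitment_kwargs) -> SimulationConfig:
    return SimulationConfig(
        recruitment=RecruitmentParams(r_mean=DESK_R_MEAN, **recruitment_kwargs)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20141203)


@pytest.fixture(scope="session")
def campaign_rv100():
    """400 ten-year simulations at Rvar = 100%, desk scale."""
    return run_campaign(desk_config(), [100.0], 400, seed=100)


@pytest.fixture(scope="session")
def campaign_rv50():
    """400 ten-year simulations at Rvar = 50%, desk scale."""
    return run_campaign(desk_config(), [50.0], 400, seed=50)


@pytest.fixture(scope="session")
def campaign_rv60():
    """250 ten-year simulations at Rvar = 60%, desk scale."""
    return run_campaign(desk_config(), [60.0], 250, seed=60)


@pytest.fixture(scope="session")
def campaign_rv30():
    """250 ten-year simulations at Rvar = 30%, desk scale."""
    return run_campaign(desk_config(), [30.0], 250, seed=30)


@pytest.fixture(scope="session")
def campaign_rv90():
    """250 ten-year simulations at Rvar = 90%, desk scale."""
    return run_campaign(desk_config(), [90.0], 250, seed=90)


@pytest.fixture(scope="session")
def campaign_all(campaign_rv30, campaign_rv50, campaign_rv60, campaign_rv90,
                 campaign_rv100):
    """Pooled multi-level campaign table (for index scoring)."""
    import pandas as pd

    frames = []
    offset = 0
    for df in (campaign_rv30, campaign_rv50, campaign_rv60, campaign_rv90,
               campaign_rv100):
        d = df.copy()
        d["sim_id"] = d["sim_id"] + offset
        offset = d["sim_id"].max() + 1
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
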