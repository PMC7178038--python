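"""Shared fixtures: the synthetic study preset, fitted once per session."""

import warnings

import pytest

from thermofold.hdx import PeakDecayModel
from thermofold.intrinsic import ExchangeConditions, krc_profile
from thermofold.simulate import acp_like_preset, simulate_hdx


@pytest.fixture(scope="session")
def preset():
    return acp_like_preset(seed=0)


@pytest.fixture(scope="session")
def preset_series(preset):
    return simulate_hdx(preset.hdx)


@pytest.fixture(scope="session")
def preset_estimates(preset, preset_series):
    """Decay-fit estimates for both pD conditions, keyed by pD then residue."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pD, series_list in preset_series.items():
            out[pD] = {
                s.residue_index: PeakDecayModel(s).fit().as_estimate()
                for s in series_list
            }
    return out


@pytest.fixture(scope="session")
def preset_krc(preset):
    rates = krc_profile(
        preset.hdx.sequence,
        ExchangeConditions(pD=6.5, temperature=preset.hdx.temperature),
    )
    return {pos: r.channel_contributions["base"] for pos, r in rates.items()}
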