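"""Shared fixtures: synthetic sessions at several scales.

All fixtures are deterministic (fixed seeds) and generated at import-time
cost only once per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fixsel.core import AnalysisConfig
from fixsel.synth import GeneratorConfig, generate_cohort, generate_session


@pytest.fixture(scope="session")
def ana_cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_session():
    """Fast structural fixture: 60 trials, 4 units."""
    cfg = GeneratorConfig(
        seed=101, n_trials=60,
        n_units_per_region={"amygdala": 2, "hippocampus_anterior": 1,
                            "hippocampus_posterior": 1},
        frac_eyes_preferring=0.25, frac_mouth_preferring=0.25)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """One session at the default study conditions (500 trials, 31 units)."""
    return generate_session(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def planted_cohort():
    """Three default sessions — enough selective units for group analyses."""
    return generate_cohort(GeneratorConfig(seed=21), 3, seed=21)


def make_unit_event_data(rates, rois, baseline=1.0, label="none",
                         unit_id="u0", serial_order=None, is_one_back=None):
    """Hand-built UnitEventData for worked examples."""
    from fixsel.selectivity import UnitEventData
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    events = pd.DataFrame({
        "event_id": [f"e{i}" for i in range(n)],
        "roi": list(rois),
        "trial_id": ["t0"] * n,
        "serial_order": serial_order if serial_order is not None else list(range(1, n + 1)),
        "is_one_back": is_one_back if is_one_back is not None else [False] * n,
        "event_type": ["fixation"] * n,
        "t_start": np.arange(n, dtype=float),
        "t_end": np.arange(n, dtype=float) + 0.4,
    })
    return UnitEventData(unit_id=unit_id, events=events, rates=rates,
                         baseline=baseline, label=label)
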