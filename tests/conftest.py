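"""Shared fixtures: the default study conditions and their (expensive) solves.

Solver runs are session-scoped so validation, metric, and acceptance tests
share one simulation per condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from atheroflow import geometry
from atheroflow.hemodynamics import solve_pulsatile
from atheroflow.synthetic import (
    SyntheticSpec,
    make_vessel_profile,
    make_waveform,
)
from atheroflow.types import FluidProperties


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


def _case(spec):
    profile = geometry.add_flow_extensions(make_vessel_profile(spec))
    return {
        "spec": spec,
        "profile": profile,
        "regions": geometry.analysis_regions(profile),
        "waveform": make_waveform(spec),
        "grid": geometry.build_grid(profile),
    }


@pytest.fixture(scope="session")
def cuffed_case():
    """Default stenotic condition: 14% residual lumen area, pulsatile inlet."""
    return _case(SyntheticSpec())


@pytest.fixture(scope="session")
def uncuffed_case():
    """Baseline/decuffed condition: uniform vessel, same inlet waveform."""
    return _case(SyntheticSpec(stenosis_area_fraction=1.0))


@pytest.fixture(scope="session")
def cuffed_run(cuffed_case):
    flow, series = solve_pulsatile(cuffed_case["grid"], cuffed_case["waveform"])
    return {"flow": flow, "series": series, **cuffed_case}


@pytest.fixture(scope="session")
def uncuffed_run(uncuffed_case):
    flow, series = solve_pulsatile(uncuffed_case["grid"], uncuffed_case["waveform"])
    return {"flow": flow, "series": series, **uncuffed_case}
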