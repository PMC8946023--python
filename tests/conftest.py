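"""Shared fixtures: default instruments and reusable synthetic studies."""

from dataclasses import replace

import pytest

from paglucose.physics import CellGeometry
from paglucose.synthetic import (
    StudyPlan,
    generate_carbon_reference,
    generate_study,
)


@pytest.fixture(scope="session")
def cell():
    return CellGeometry()


@pytest.fixture(scope="session")
def plan():
    return StudyPlan()


@pytest.fixture(scope="session")
def noise_free_plan(plan):
    return plan.noise_free()


@pytest.fixture(scope="session")
def carbon(plan, cell):
    return generate_carbon_reference(
        plan.grid,
        cell,
        floor=plan.carbon_floor,
        heights=plan.carbon_heights,
        width_scale=plan.carbon_width_scale,
    )


@pytest.fixture(scope="session")
def default_study(plan, cell):
    """One full default study (300 records), generated once per session."""
    return generate_study(plan, seed=7, cell=cell)


@pytest.fixture(scope="session")
def small_plan(plan):
    """A one-day, four-class plan for fast classifier tests."""
    return replace(
        plan,
        days=1,
        rounds_per_day=10,
        concentrations=(75.0, 150.0, 225.0, 300.0),
    )
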