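"""Shared fixtures: small synthetic scenarios generated at test time."""

import dataclasses

import numpy as np
import pytest

from c1screen.geometry import LigandSpec
from c1screen.synthgen import ScenarioConfig, generate_scenario, reference_scenarios


def small_config(**overrides) -> ScenarioConfig:
    """A fast reduced scenario: fewer waters/frames than the defaults."""
    base = dict(n_lipids=16, n_waters=60, n_ions=4, n_frames=50, seed=11)
    base.update(overrides)
    return ScenarioConfig(**base)


def scenario_with(name: str, seed: int = 0, **overrides):
    cfg = reference_scenarios(seed=seed)[name]
    if overrides:
        cfg = ScenarioConfig(**{**dataclasses.asdict(cfg), **overrides})
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def hmi_small():
    """Reduced hmi_like scenario shared across tests (read-only)."""
    traj, groups, gt = scenario_with(
        "hmi_like", seed=5, n_waters=120, n_ions=4, n_frames=60
    )
    spec = LigandSpec.from_selection_groups(groups, "LIG", 4)
    return traj, groups, spec, gt


@pytest.fixture(scope="session")
def pyr_small():
    traj, groups, gt = scenario_with(
        "pyr_like", seed=5, n_waters=120, n_ions=4, n_frames=60
    )
    spec = LigandSpec.from_selection_groups(groups, "LIG", 4)
    return traj, groups, spec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
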