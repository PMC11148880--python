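"""Shared fixtures: phantoms, plan states and a toy scoring setup.

Expensive objects (the mini plan state and its environment) are built once
per session; tests that mutate environment state must call ``reset`` first.
"""

from __future__ import annotations

import numpy as np
import pytest

from rtautoplan.geometry import (
    StructureSet,
    VoxelGrid,
    derive_auxiliary_structures,
    generate_phantom,
    mini_phantom_spec,
)
from rtautoplan.scoring import load_scoring_config
from rtautoplan.workflow import PlanningEnv, initialize_plan


@pytest.fixture(scope="session")
def mini_structures() -> StructureSet:
    return derive_auxiliary_structures(generate_phantom(mini_phantom_spec()))


@pytest.fixture(scope="session")
def mini_state():
    return initialize_plan(mini_phantom_spec())


@pytest.fixture(scope="session")
def mini_env(mini_state) -> PlanningEnv:
    return PlanningEnv(mini_state, max_steps=10)


@pytest.fixture(scope="session")
def scoring_config():
    return load_scoring_config()


@pytest.fixture(scope="session")
def toy_scored_structures(scoring_config):
    """A small structure set in which every scored structure is a disjoint
    block, so per-structure doses can be assigned independently."""
    grid = VoxelGrid((16, 16, 1), (10.0, 10.0, 10.0))
    ss = StructureSet(grid=grid)
    body = np.ones(grid.shape, dtype=bool)
    ss.add("BODY", body, "body")
    names = sorted({m.structure for m in scoring_config.metrics} - {"BODY"})
    n_each = 4  # keep the target fraction of the body small
    flat_index = np.arange(grid.n_voxels).reshape(grid.shape)
    for k, name in enumerate(names):
        mask = (flat_index >= k * n_each) & (flat_index < (k + 1) * n_each)
        role = "target" if name.startswith(("PTV", "CTV")) else "organ"
        ss.add(name, mask, role)
    return ss


@pytest.fixture(scope="session")
def toy_full_credit_dose(toy_scored_structures) -> np.ndarray:
    """A synthetic dose hitting every metric's full-credit plateau on the
    disjoint-block structure set: prescription-level dose in each target
    block, zero elsewhere."""
    ss = toy_scored_structures
    rx = {"63": 6300.0, "60": 6000.0, "57": 5700.0, "54": 5400.0}
    d = np.zeros(ss.grid.n_voxels)
    for name, mask in ss.masks.items():
        for lvl, dose in rx.items():
            if name in (f"PTV{lvl}", f"CTV{lvl}"):
                d[mask.ravel()] = dose
    return d
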