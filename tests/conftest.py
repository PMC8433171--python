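import numpy as np
import pytest

import striderswarm as sw


@pytest.fixture
def params() -> sw.SimulationParams:
    return sw.SimulationParams()


@pytest.fixture
def quiet_params() -> sw.SimulationParams:
    """Deterministic dynamics only: no births, no food, no mass loss."""
    return sw.SimulationParams().replace(p_birth=0.0, p_food=0.0, lam=0.0)


def make_pair_state(p: sw.SimulationParams, separation: float, mass: float = 1.0) -> sw.SimulationState:
    """Two equal-mass animals at rest, centred in the arena, split along x."""
    state = sw.init_state(p.replace(N0=0))
    cx, cy = p.Lx / 2.0, p.Ly / 2.0
    state.r = np.array([[cx - separation / 2.0, cy], [cx + separation / 2.0, cy]])
    state.v = np.zeros((2, 2))
    state.m = np.full(2, float(mass))
    state.ids = np.arange(2, dtype=np.int64)
    state.t_birth = np.zeros(2)
    state.n0 = 2
    state.next_animal_id = 2
    return state


def make_population_state(p: sw.SimulationParams, r: np.ndarray, m: np.ndarray) -> sw.SimulationState:
    """A state with prescribed positions and masses, at rest."""
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    state = sw.init_state(p.replace(N0=0))
    state.r = r.copy()
    state.v = np.zeros_like(r)
    state.m = m.copy()
    state.ids = np.arange(len(m), dtype=np.int64)
    state.t_birth = np.zeros(len(m))
    state.n0 = len(m)
    state.next_animal_id = len(m)
    return state


def add_food(state: sw.SimulationState, positions, amounts) -> sw.SimulationState:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    amounts = np.atleast_1d(np.asarray(amounts, dtype=float))
    state.food_r = positions.copy()
    state.food_remaining = amounts.copy()
    state.food_ids = np.arange(len(amounts), dtype=np.int64)
    state.next_food_id = len(amounts)
    state.food_deposited += float(amounts[np.isfinite(amounts)].sum())
    return state
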