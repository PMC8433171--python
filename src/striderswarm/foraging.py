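"""Food deposition, proximity-gated consumption, portion depletion, mass loss.

A portion appears with per-step probability p_food at a uniform-random spot,
holding q_food units of edible mass.  An animal within R_food_thres of a
portion feeds from the nearest one (ties broken toward the oldest portion)
at the mass-proportional rate dm/dt = mu * m; competitors at the same portion
split what is left in proportion to their demands, so a portion is emptied
exactly, never overdrawn.  Exhausted portions disappear.  Every animal then
pays the metabolic cost lam * m * dt on its post-meal mass.

With lam = 0, cumulative intake + remaining food == cumulative deposits —
food mass is conserved to rounding error.
"""
from __future__ import annotations

import numpy as np

from .core import SimulationParams, SimulationState

__all__ = ["maybe_deposit_food", "consume_and_grow"]

_EMPTY_TOL = 1e-12


def maybe_deposit_food(state: SimulationState, p: SimulationParams) -> SimulationState:
    """One deposition trial; draw order: food test -> position."""
    if state.rng.random() < p.p_food:
        pos = state.rng.random(2) * np.array([p.Lx, p.Ly])
        state.food_r = np.vstack([state.food_r, pos[None, :]])
        state.food_remaining = np.append(state.food_remaining, p.q_food)
        state.food_ids = np.append(state.food_ids, state.next_food_id)
        state.next_food_id += 1
        state.food_deposited += p.q_food
    return state


def consume_and_grow(state: SimulationState, p: SimulationParams) -> SimulationState:
    """One feeding/metabolism update over dt."""
    if state.n > 0 and state.n_food > 0:
        dx = state.r[:, None, :] - state.food_r[None, :, :]
        d2 = np.einsum("jnc,jnc->jn", dx, dx)
        nearest = np.argmin(d2, axis=1)  # first minimum -> lowest (oldest) id
        in_range = d2[np.arange(state.n), nearest] < p.R_food_thres**2
        if in_range.any():
            eaters = np.flatnonzero(in_range)
            portion = nearest[eaters]
            demand = p.mu * state.m[eaters] * p.dt
            total_demand = np.bincount(portion, weights=demand, minlength=state.n_food)
            avail = state.food_remaining
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(total_demand > avail, avail / total_demand, 1.0)
            intake = demand * scale[portion]
            state.m = state.m.copy()
            state.m[eaters] += intake
            taken = np.bincount(portion, weights=intake, minlength=state.n_food)
            state.food_remaining = avail - taken
            state.food_consumed += float(intake.sum())
            tol = _EMPTY_TOL * (p.q_food if np.isfinite(p.q_food) else 1.0)
            empty = state.food_remaining <= tol
            if empty.any():
                keep = ~empty
                state.food_r = state.food_r[keep]
                state.food_remaining = state.food_remaining[keep]
                state.food_ids = state.food_ids[keep]
    if p.lam > 0.0 and state.n > 0:
        state.m = state.m * (1.0 - p.lam * p.dt)
    return state
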