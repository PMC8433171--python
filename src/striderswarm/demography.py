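"""Recruitment of small individuals, removal at critical masses, size classes.

Recruitment is one threshold test per time step: draw u ~ U[0, 1]; if
u < p_birth a single newborn appears at a uniform-random spot with zero
velocity and a mass uniform in [m_s - m_s_spread, m_s + m_s_spread].
Removal is immediate and inclusive: any animal with m <= m_min (starved) or
m >= m_max (fully grown, leaves the population) disappears in the cull phase.
Both exits are tallied separately but sum to the cumulative "died/left" count.
"""
from __future__ import annotations

import numpy as np

from .core import SimulationParams, SimulationState

__all__ = ["maybe_recruit", "cull", "classify_size", "class_counts", "CLASS_LABELS"]

CLASS_LABELS = ("small", "medium", "large")


def maybe_recruit(state: SimulationState, p: SimulationParams) -> SimulationState:
    """One recruitment trial; draw order: birth test -> position -> mass."""
    if state.rng.random() < p.p_birth:
        pos = state.rng.random(2) * np.array([p.Lx, p.Ly])
        mass = p.m_s + (2.0 * state.rng.random() - 1.0) * p.m_s_spread
        state.r = np.vstack([state.r, pos[None, :]])
        state.v = np.vstack([state.v, np.zeros((1, 2))])
        state.m = np.append(state.m, mass)
        state.ids = np.append(state.ids, state.next_animal_id)
        state.t_birth = np.append(state.t_birth, state.t)
        state.next_animal_id += 1
        state.n_born += 1
    return state


def cull(state: SimulationState, p: SimulationParams) -> SimulationState:
    """Remove every animal at or beyond a critical mass; update counters."""
    at_min = state.m <= p.m_min
    at_max = state.m >= p.m_max
    gone = at_min | at_max
    if gone.any():
        state.n_died_min += int(at_min.sum())
        state.n_died_max += int((at_max & ~at_min).sum())
        keep = ~gone
        state.r = state.r[keep]
        state.v = state.v[keep]
        state.m = state.m[keep]
        state.ids = state.ids[keep]
        state.t_birth = state.t_birth[keep]
    return state


def classify_size(m, p: SimulationParams):
    """Size class codes: 0 small, 1 medium, 2 large (left-closed intervals).

    m < m_class12 -> small; m_class12 <= m < m_class23 -> medium;
    m >= m_class23 -> large.  Works elementwise on arrays.
    """
    m = np.asarray(m, dtype=float)
    codes = np.zeros(m.shape, dtype=np.int64)
    codes[m >= p.m_class12] = 1
    codes[m >= p.m_class23] = 2
    return codes if codes.ndim else int(codes)


def class_counts(state: SimulationState, p: SimulationParams) -> np.ndarray:
    """(N_small, N_medium, N_large) for the current population."""
    if state.n == 0:
        return np.zeros(3, dtype=np.int64)
    return np.bincount(classify_size(state.m, p), minlength=3)
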