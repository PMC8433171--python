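"""Force laws: Gaussian pair repulsion/attraction, soft walls, food pull,
wave-of-fear forcing, mass scalings, and the analytic equilibrium distance.

Pair forces use a Gaussian kernel ``B * (r_j - r_k) * exp(-d^2 / R^2)``, which
is smooth at contact (the prefactor vanishes at zero separation) and decays
fast enough that a pair farther apart than a few radii is effectively
non-interacting.  Amplitudes scale with individual strength (mass^alpha,
alpha = 2/3 by default) and radii with body length (mass^beta, beta = 1/3),
so larger animals claim larger private territories and push harder.
"""
from __future__ import annotations

import math

import numpy as np

from .core import ParameterError, SimulationParams, SimulationState

__all__ = [
    "pair_repulsion",
    "pair_attraction",
    "pair_amplitude_radius",
    "boundary_force",
    "food_force",
    "damping_coefficient",
    "wave_active",
    "wave_force",
    "equilibrium_distance",
    "total_forces",
]


def _check_radius(R: float) -> None:
    if R <= 0:
        raise ParameterError(f"interaction radius must be positive (got {R})")


def pair_repulsion(r_j: np.ndarray, r_k: np.ndarray, B_jk: float, R_jk: float) -> np.ndarray:
    """Gaussian repulsion on animal j from animal k.

    ``f = B * (r_j - r_k) * exp(-|r_j - r_k|^2 / R^2)``; for B > 0 the force
    points from k toward j.  Vanishes at zero separation.
    """
    _check_radius(R_jk)
    dr = np.asarray(r_j, dtype=float) - np.asarray(r_k, dtype=float)
    return B_jk * dr * math.exp(-float(dr @ dr) / R_jk**2)


def pair_attraction(r_j: np.ndarray, r_k: np.ndarray, B_jk: float, R_jk: float) -> np.ndarray:
    """Gaussian attraction on j toward k (B_jk stored positive)."""
    _check_radius(R_jk)
    dr = np.asarray(r_j, dtype=float) - np.asarray(r_k, dtype=float)
    return -B_jk * dr * math.exp(-float(dr @ dr) / R_jk**2)


def pair_amplitude_radius(m_j: float, m_k: float, p: SimulationParams):
    """Per-pair amplitudes and radii for a (j, k) pair of masses.

    Amplitude = prefactor * mean of the two strengths (m^alpha each);
    radius = prefactor * mean of the two body-length scales (m^beta each).
    Symmetric in (j, k) so pair forces obey Newton's third law.
    """
    s = 0.5 * (m_j**p.alpha_exp + m_k**p.alpha_exp)
    ell = 0.5 * (m_j**p.beta_exp + m_k**p.beta_exp)
    return (p.B_repuls0 * s, p.R_repuls0 * ell, p.B_attract0 * s, p.R_attract0 * ell)


def boundary_force(r_j: np.ndarray, p: SimulationParams) -> np.ndarray:
    """Soft exponential walls at x=0, x=Lx, y=0, y=Ly, superposed.

    Each wall pushes inward with magnitude ``B_bound * exp(-d / R_bound)``
    where d is the signed perpendicular distance to the wall; an animal that
    has crossed a wall (d < 0) feels an exponentially growing restoring force.
    """
    r = np.asarray(r_j, dtype=float)
    x, y = r[..., 0], r[..., 1]
    B, R = p.B_bound, p.R_bound
    # exponent capped so a deep excursion gives a huge finite kick, not inf
    def wall(d):
        return B * np.exp(np.minimum(-d / R, 40.0))
    fx = wall(x) - wall(p.Lx - x)
    fy = wall(y) - wall(p.Ly - y)
    return np.stack([fx, fy], axis=-1)


def food_force(r_j: np.ndarray, m_j: float, r_n: np.ndarray, p: SimulationParams) -> np.ndarray:
    """Attraction of animal j (mass m_j) toward food portion at r_n.

    Amplitude scales with foraging strength, ``B_food0 * m^alpha``; radius is
    the mass-independent detection range R_food.
    """
    dr = np.asarray(r_j, dtype=float) - np.asarray(r_n, dtype=float)
    B = p.B_food0 * m_j**p.alpha_exp
    return -B * dr * math.exp(-float(dr @ dr) / p.R_food**2)


def damping_coefficient(m_j, p: SimulationParams):
    """Surface drag eta = eta0 * m^beta (leg span grows with body length)."""
    return p.eta0 * np.asarray(m_j, dtype=float) ** p.beta_exp


def wave_active(t: float, p: SimulationParams) -> bool:
    """True while a periodic fear wave is running at time t."""
    if not p.waves_enabled:
        return False
    return (t % p.wave_period) < p.wave_duration


def wave_force(r_j: np.ndarray, m_j, t: float, p: SimulationParams) -> np.ndarray:
    """Wave-of-fear push from the dangerous wall x = 0.

    During an active window the wall emits a long-range exponential force
    ``B_wave * m^alpha * exp(-x / R_wave)`` directed into the arena (+x).
    The m^alpha amplitude scaling makes the terminal escape drift grow as
    m^(alpha-beta) = m^(1/3): big, strong animals flee farther and faster.
    Zero outside active windows or when waves are disabled.
    """
    r = np.asarray(r_j, dtype=float)
    m = np.asarray(m_j, dtype=float)
    out = np.zeros(np.broadcast_shapes(r.shape[:-1], m.shape) + (2,))
    if p.B_wave == 0.0 or not wave_active(t, p):
        return out
    x = r[..., 0]
    out[..., 0] = p.B_wave * m**p.alpha_exp * np.exp(-x / p.R_wave)
    return out


def equilibrium_distance(m: float, p: SimulationParams) -> float:
    """Separation R_min where repulsion and attraction balance for an
    equal-mass pair.

    Setting |f_rep| = |f_att| in the Gaussian pair laws gives the closed form
    ``R_min = sqrt( ln(B_rep/B_att) / (1/R_rep^2 - 1/R_att^2) )`` with the
    (j,k)-resolved amplitudes and radii.  Because B and R scale with the same
    mass factors for repulsion and attraction, R_min of a pair scales as the
    body length, m^beta.
    """
    B_rep, R_rep, B_att, R_att = pair_amplitude_radius(m, m, p)
    if B_rep <= B_att:
        raise ParameterError(
            f"no interior energy minimum: require B_rep > B_att (got {B_rep} <= {B_att})"
        )
    denom = 1.0 / R_rep**2 - 1.0 / R_att**2
    if denom <= 0:
        raise ParameterError(
            f"no interior energy minimum: require R_att > R_rep (got R_rep={R_rep}, R_att={R_att})"
        )
    return math.sqrt(math.log(B_rep / B_att) / denom)


# ---------------------------------------------------------------------------
# vectorized total force
# ---------------------------------------------------------------------------

def total_forces(state: SimulationState, p: SimulationParams, t: float | None = None,
                 components: bool = False):
    """Per-animal net force (N, 2) at time t; O(N^2) pairwise evaluation.

    With ``components=True`` also returns a dict of the labelled parts
    (pair, boundary, food, wave) for diagnostics.
    """
    if t is None:
        t = state.t
    n = state.n
    r, m = state.r, state.m
    pair = np.zeros((n, 2))
    if n >= 2:
        s = m**p.alpha_exp
        ell = m**p.beta_exp
        dx = r[:, None, :] - r[None, :, :]            # (N, N, 2)
        d2 = np.einsum("jkc,jkc->jk", dx, dx)
        S = 0.5 * (s[:, None] + s[None, :])           # pair strength factor
        L = 0.5 * (ell[:, None] + ell[None, :])       # pair length factor
        L2 = L * L
        w_rep = (p.B_repuls0 * S) * np.exp(-d2 / (p.R_repuls0**2 * L2))
        w_att = (p.B_attract0 * S) * np.exp(-d2 / (p.R_attract0**2 * L2))
        w = w_rep - w_att
        np.fill_diagonal(w, 0.0)
        pair = np.einsum("jk,jkc->jc", w, dx)
    bound = boundary_force(r, p)
    food = np.zeros((n, 2))
    if n >= 1 and state.n_food >= 1:
        dxf = r[:, None, :] - state.food_r[None, :, :]   # (N, M, 2)
        d2f = np.einsum("jnc,jnc->jn", dxf, dxf)
        Bf = p.B_food0 * m**p.alpha_exp
        wf = np.exp(-d2f / p.R_food**2)
        food = -Bf[:, None, None] * wf[:, :, None] * dxf
        food = food.sum(axis=1)
    wave = wave_force(r, m, t, p) if p.waves_enabled else np.zeros((n, 2))
    tot = pair + bound + food + wave
    if components:
        return tot, {"pair": pair, "boundary": bound, "food": food, "wave": wave}
    return tot
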