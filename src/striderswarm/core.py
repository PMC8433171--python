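"""Domain types, parameter validation, and the seeded-randomness contract.

All model quantities are in abstract model units (length, time, mass); no SI
scale is implied.  Every stochastic procedure in the simulator draws from the
single :class:`numpy.random.Generator` stored on the state, in a fixed,
documented order (see :mod:`striderswarm.dynamics`), so a run is bit-identical
for identical ``(params, seed)``.
"""
from __future__ import annotations

import copy
import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ParameterError",
    "SimulationParams",
    "AnimalState",
    "FoodItem",
    "SimulationState",
    "validate_params",
    "init_state",
    "check_bookkeeping",
    "params_to_config",
    "params_from_config",
    "save_config",
    "load_config",
    "params_hash",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates a model inequality."""


@dataclass(frozen=True)
class SimulationParams:
    """Every model constant: arena, forces, rates, thresholds, schedules.

    The defaults define the package's baseline scenario: a ~100-strong
    water-strider group on a 30x30 water surface with short-range repulsion
    (radius 1), weaker long-range attraction (radius 3), stiff soft walls,
    and food/demography rates balanced so the population settles into a
    quasi-stationary state within a few hundred time units.
    """

    # arena & integration
    Lx: float = 30.0
    Ly: float = 30.0
    dt: float = 0.02

    # pair interactions (unit-mass prefactors; per-pair values scale with mass)
    B_repuls0: float = 2.0
    R_repuls0: float = 1.0
    B_attract0: float = 0.05
    R_attract0: float = 2.0

    # soft boundary walls
    B_bound: float = 20.0
    R_bound: float = 0.4

    # food attraction & consumption gate
    B_food0: float = 2.0
    R_food: float = 3.0
    R_food_thres: float = 0.5

    # mass-scaling exponents (strength ~ m^(2/3), body length / damping ~ m^(1/3))
    alpha_exp: float = 2.0 / 3.0
    beta_exp: float = 1.0 / 3.0

    # damping & metabolic rates
    eta0: float = 1.0
    mu: float = 0.2
    lam: float = 0.01

    # recruit mass window and critical masses
    m_s: float = 1.0
    m_s_spread: float = 0.2
    m_min: float = 0.5
    m_max: float = 4.0

    # stochastic event thresholds (per-step probabilities) and portion size
    p_birth: float = 0.02
    p_food: float = 0.015
    q_food: float = 2.0

    # wave-of-fear forcing from the dangerous wall x = 0
    B_wave: float = 0.0
    R_wave: float = 10.0
    wave_period: float = 0.0
    wave_duration: float = 5.0

    # size-class boundaries (small | medium | large)
    m_class12: float = 5.0 / 3.0   # m_min + (m_max - m_min)/3
    m_class23: float = 17.0 / 6.0  # m_min + 2*(m_max - m_min)/3

    # initial population
    N0: int = 100
    m_init_mean: float = 1.0
    m_init_spread: float = 0.2

    seed: int = 12345

    # -- convenience ---------------------------------------------------
    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    @property
    def waves_enabled(self) -> bool:
        return self.B_wave > 0.0 and self.wave_period > 0.0


_INT_FIELDS = {"N0", "seed"}


def validate_params(p: SimulationParams) -> SimulationParams:
    """Check every model inequality; return ``p`` unchanged if all hold.

    Raises :class:`ParameterError` naming the first violated constraint.
    """

    def req(cond: bool, msg: str) -> None:
        if not cond:
            raise ParameterError(msg)

    req(p.Lx > 0 and p.Ly > 0, f"arena sides must be positive (Lx={p.Lx}, Ly={p.Ly})")
    req(p.dt > 0, f"time step dt must be positive (dt={p.dt})")
    req(p.B_repuls0 > 0, f"repulsion amplitude B_repuls0 must be > 0 (got {p.B_repuls0})")
    req(p.R_repuls0 > 0, f"repulsion radius R_repuls0 must be > 0 (got {p.R_repuls0})")
    req(p.B_attract0 > 0, f"attraction amplitude B_attract0 must be > 0 (got {p.B_attract0})")
    req(
        p.B_attract0 < p.B_repuls0,
        "attraction must be weaker than repulsion: require B_attract0 < B_repuls0 "
        f"(got B_attract0={p.B_attract0}, B_repuls0={p.B_repuls0})",
    )
    req(
        p.R_attract0 > p.R_repuls0,
        "attraction must be longer-ranged than repulsion: require R_attract0 > R_repuls0 "
        f"(got R_attract0={p.R_attract0}, R_repuls0={p.R_repuls0})",
    )
    req(p.B_bound > p.B_repuls0, f"boundary wall must overpower pair repulsion: B_bound > B_repuls0 (got {p.B_bound})")
    req(p.R_bound > 0, f"boundary decay length R_bound must be > 0 (got {p.R_bound})")
    req(p.B_food0 > 0 and p.R_food > 0, "food attraction amplitude and radius must be positive")
    req(p.R_food_thres > 0, f"consumption gate R_food_thres must be > 0 (got {p.R_food_thres})")
    req(p.eta0 > 0, f"damping prefactor eta0 must be > 0 (got {p.eta0})")
    req(p.mu > 0, f"assimilation rate mu must be > 0 (got {p.mu})")
    req(p.lam >= 0, f"loss rate lam must be >= 0 (got {p.lam})")
    req(p.m_min < p.m_max, f"mass window degenerate: require m_min < m_max (got {p.m_min}, {p.m_max})")
    req(0 <= p.m_s_spread < p.m_s, f"recruit spread must satisfy 0 <= m_s_spread < m_s (got {p.m_s_spread})")
    req(
        p.m_min < p.m_s - p.m_s_spread,
        f"recruit masses must lie above m_min: require m_min < m_s - m_s_spread "
        f"(got m_min={p.m_min}, m_s-m_s_spread={p.m_s - p.m_s_spread})",
    )
    req(
        p.m_s + p.m_s_spread < p.m_max,
        f"recruit masses must lie below m_max: require m_s + m_s_spread < m_max "
        f"(got m_s+m_s_spread={p.m_s + p.m_s_spread}, m_max={p.m_max})",
    )
    req(
        p.m_min < p.m_init_mean - p.m_init_spread and p.m_init_mean + p.m_init_spread < p.m_max,
        "initial masses must lie strictly inside (m_min, m_max) "
        f"(got m_init_mean={p.m_init_mean} +/- {p.m_init_spread})",
    )
    req(0.0 <= p.p_birth <= 1.0, f"p_birth must be a probability in [0, 1] (got {p.p_birth})")
    req(0.0 <= p.p_food <= 1.0, f"p_food must be a probability in [0, 1] (got {p.p_food})")
    req(p.q_food > 0, f"food portion capacity q_food must be > 0 (got {p.q_food})")
    req(
        p.m_min < p.m_class12 < p.m_class23 < p.m_max,
        "size-class boundaries must satisfy m_min < m_class12 < m_class23 < m_max "
        f"(got {p.m_class12}, {p.m_class23})",
    )
    req(p.N0 >= 0, f"initial population N0 must be >= 0 (got {p.N0})")
    if p.waves_enabled:
        req(
            p.B_wave > p.B_bound,
            f"fear wave must overpower the wall: require B_wave > B_bound (got B_wave={p.B_wave}, B_bound={p.B_bound})",
        )
        req(
            p.R_wave > p.R_bound,
            f"fear wave must reach much farther than the wall: require R_wave > R_bound "
            f"(got R_wave={p.R_wave}, R_bound={p.R_bound})",
        )
        req(
            0 < p.wave_duration < p.wave_period,
            f"wave schedule requires 0 < wave_duration < wave_period (got {p.wave_duration}, {p.wave_period})",
        )
    # soft check: dt should resolve the fastest velocity-relaxation time m/eta
    # over the recruit-mass range, or trajectories lose accuracy
    m_lo = min(p.m_s - p.m_s_spread, p.m_init_mean - p.m_init_spread)
    tau_min = m_lo / (p.eta0 * m_lo**p.beta_exp)
    if p.dt > 0.05 * tau_min:
        warnings.warn(
            f"dt={p.dt} exceeds 0.05 * min(m/eta)={0.05 * tau_min:.4g}; "
            "integration may be too coarse for accurate relaxation dynamics",
            RuntimeWarning,
            stacklevel=2,
        )
    return p


@dataclass(frozen=True)
class AnimalState:
    """Read-only view of one individual."""

    id: int
    r: np.ndarray  # (2,) position
    v: np.ndarray  # (2,) velocity
    m: float
    t_birth: float


@dataclass(frozen=True)
class FoodItem:
    """Read-only view of one deposited food portion."""

    id: int
    r: np.ndarray  # (2,) position
    remaining: float


@dataclass
class SimulationState:
    """Full mutable simulation state; animals and food live in flat arrays.

    Array-of-struct views (:attr:`animals`, :attr:`food_items`) are built on
    demand; the hot loops operate on the arrays directly.
    """

    t: float
    r: np.ndarray         # (N, 2)
    v: np.ndarray         # (N, 2)
    m: np.ndarray         # (N,)
    ids: np.ndarray       # (N,) int64
    t_birth: np.ndarray   # (N,)
    food_r: np.ndarray            # (M, 2)
    food_remaining: np.ndarray    # (M,)
    food_ids: np.ndarray          # (M,) int64
    rng: np.random.Generator
    n0: int
    n_born: int = 0
    n_died_min: int = 0
    n_died_max: int = 0
    next_animal_id: int = 0
    next_food_id: int = 0
    food_deposited: float = 0.0   # cumulative deposited food mass
    food_consumed: float = 0.0    # cumulative mass assimilated from portions

    @property
    def n(self) -> int:
        return self.m.shape[0]

    @property
    def n_food(self) -> int:
        return self.food_remaining.shape[0]

    @property
    def n_removed(self) -> int:
        return self.n_died_min + self.n_died_max

    @property
    def animals(self) -> list[AnimalState]:
        return [
            AnimalState(int(self.ids[j]), self.r[j].copy(), self.v[j].copy(),
                        float(self.m[j]), float(self.t_birth[j]))
            for j in range(self.n)
        ]

    @property
    def food_items(self) -> list[FoodItem]:
        return [
            FoodItem(int(self.food_ids[k]), self.food_r[k].copy(), float(self.food_remaining[k]))
            for k in range(self.n_food)
        ]

    def copy(self) -> "SimulationState":
        """Deep copy including the RNG stream position."""
        return copy.deepcopy(self)

    def __iter__(self) -> Iterator[AnimalState]:
        return iter(self.animals)


def check_bookkeeping(state: SimulationState) -> None:
    """Assert the population balance N0 + born - removed == N."""
    expected = state.n0 + state.n_born - state.n_removed
    if expected != state.n:
        raise AssertionError(
            f"population bookkeeping broken: N0({state.n0}) + born({state.n_born}) "
            f"- removed({state.n_removed}) = {expected} != N({state.n})"
        )


def init_state(p: SimulationParams) -> SimulationState:
    """Build the initial state: N0 animals at rest, uniform positions/masses.

    Draw order (reproducibility contract): all positions first, then all
    masses, from the single stream seeded with ``p.seed``.
    """
    validate_params(p)
    rng = np.random.default_rng(p.seed)
    n = p.N0
    r = rng.random((n, 2)) * np.array([p.Lx, p.Ly])
    m = p.m_init_mean + (2.0 * rng.random(n) - 1.0) * p.m_init_spread
    return SimulationState(
        t=0.0,
        r=r,
        v=np.zeros((n, 2)),
        m=m,
        ids=np.arange(n, dtype=np.int64),
        t_birth=np.zeros(n),
        food_r=np.empty((0, 2)),
        food_remaining=np.empty(0),
        food_ids=np.empty(0, dtype=np.int64),
        rng=rng,
        n0=n,
        next_animal_id=n,
    )


# ---------------------------------------------------------------------------
# flat key = value config round-trip
# ---------------------------------------------------------------------------

def params_to_config(p: SimulationParams) -> str:
    """Serialize parameters to a flat ``key = value`` text block."""
    lines = ["# striderswarm run configuration (model units)"]
    for f in dataclasses.fields(p):
        lines.append(f"{f.name} = {getattr(p, f.name)!r}")
    return "\n".join(lines) + "\n"


def params_from_config(text: str) -> SimulationParams:
    """Parse a flat config; unknown or missing keys are errors."""
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    values: dict[str, float | int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"config line {lineno} is not 'key = value': {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ParameterError(f"unknown config key {key!r} on line {lineno}")
        if key in values:
            raise ParameterError(f"duplicate config key {key!r} on line {lineno}")
        try:
            values[key] = int(val) if key in _INT_FIELDS else float(val)
        except ValueError as exc:
            raise ParameterError(f"cannot parse value for {key!r}: {val!r}") from exc
    missing = sorted(known - values.keys())
    if missing:
        raise ParameterError(f"missing required config key(s): {', '.join(missing)}")
    return SimulationParams(**values)


def save_config(p: SimulationParams, path: str | Path) -> None:
    Path(path).write_text(params_to_config(p))


def load_config(path: str | Path) -> SimulationParams:
    return params_from_config(Path(path).read_text())


def params_hash(p: SimulationParams) -> str:
    """Stable short hash of the full parameter set (for run logs)."""
    return hashlib.sha256(params_to_config(p).encode()).hexdigest()[:16]
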