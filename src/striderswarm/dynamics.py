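"""Time stepping: damped-inertial integration plus the per-step event phases.

Equation of motion per animal:  m dv/dt = F(r, t) - eta(m) v,  with F the sum
of pair, boundary, food and wave forces.  The velocity update is the exact
solution of this linear ODE for a force held constant over the step,

    v <- F/eta + (v - F/eta) * exp(-dt * eta / m),    r <- r + dt * v,

which is unconditionally stable under strong damping and reproduces free
velocity decay exactly at any dt.

Each step runs a fixed phase schedule (part of the reproducibility contract —
reordering changes trajectories):

    1. force evaluation      (no RNG)
    2. integration           (no RNG)
    3. consumption & mass update (no RNG)
    4. cull at critical masses   (no RNG)
    5. recruitment           (draws: birth test, position, mass)
    6. food deposition       (draws: food test, position)
    7. recording

A newborn therefore cannot be culled in its own birth step.  All draws come
from the single stream in the order listed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography, foraging
from .core import (SimulationParams, SimulationState, check_bookkeeping,
                   init_state, params_hash, params_to_config, validate_params)
from .forces import damping_coefficient, total_forces

__all__ = ["STEP_SCHEDULE", "integrate_step", "step", "run", "RunRecord", "Snapshot"]

STEP_SCHEDULE = (
    "forces",
    "integrate",
    "consume_and_grow",
    "cull",
    "recruit",
    "deposit_food",
    "record",
)


class NumericalError(RuntimeError):
    """A non-finite force or coordinate appeared during integration."""


def integrate_step(state: SimulationState, forces: np.ndarray, p: SimulationParams) -> SimulationState:
    """Advance positions and velocities by dt under the given forces.

    Masses are untouched here.  Aborts with a diagnostic naming the animal
    and phase if anything non-finite appears.
    """
    if state.n == 0:
        return state
    if not np.isfinite(forces).all():
        bad = int(state.ids[np.flatnonzero(~np.isfinite(forces).all(axis=1))[0]])
        raise NumericalError(f"non-finite force on animal id={bad} at t={state.t:.6g} (phase: integrate)")
    eta = damping_coefficient(state.m, p)
    decay = np.exp(-p.dt * eta / state.m)
    v_inf = forces / eta[:, None]
    state.v = v_inf + (state.v - v_inf) * decay[:, None]
    state.r = state.r + p.dt * state.v
    if not np.isfinite(state.r).all():
        bad = int(state.ids[np.flatnonzero(~np.isfinite(state.r).all(axis=1))[0]])
        raise NumericalError(f"non-finite position of animal id={bad} at t={state.t:.6g} (phase: integrate)")
    return state


def step(state: SimulationState, p: SimulationParams) -> SimulationState:
    """Run the phase schedule once; t advances by dt."""
    f = total_forces(state, p, t=state.t)
    integrate_step(state, f, p)
    foraging.consume_and_grow(state, p)
    demography.cull(state, p)
    demography.maybe_recruit(state, p)
    foraging.maybe_deposit_food(state, p)
    state.t += p.dt
    return state


@dataclass(frozen=True)
class Snapshot:
    """One recorded instant of the population and food field."""

    step: int
    t: float
    ids: np.ndarray
    r: np.ndarray
    v: np.ndarray
    m: np.ndarray
    food_r: np.ndarray
    food_remaining: np.ndarray

    @property
    def n(self) -> int:
        return self.m.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v[:, 0], self.v[:, 1])


@dataclass
class RunRecord:
    """Recorded time series of a run: snapshots plus demographic counters."""

    params: SimulationParams
    snapshots: list[Snapshot] = field(default_factory=list)
    # counter series, one row per recorded step
    rec_steps: list[int] = field(default_factory=list)
    rec_t: list[float] = field(default_factory=list)
    rec_n: list[int] = field(default_factory=list)
    rec_classes: list[np.ndarray] = field(default_factory=list)
    rec_born: list[int] = field(default_factory=list)
    rec_died: list[int] = field(default_factory=list)
    rec_nfood: list[int] = field(default_factory=list)
    extinctions: list[float] = field(default_factory=list)
    final_state: SimulationState | None = None

    def record(self, istep: int, state: SimulationState) -> None:
        self.snapshots.append(
            Snapshot(istep, state.t, state.ids.copy(), state.r.copy(), state.v.copy(),
                     state.m.copy(), state.food_r.copy(), state.food_remaining.copy())
        )
        self.rec_steps.append(istep)
        self.rec_t.append(state.t)
        self.rec_n.append(state.n)
        self.rec_classes.append(demography.class_counts(state, self.params))
        self.rec_born.append(state.n_born)
        self.rec_died.append(state.n_removed)
        self.rec_nfood.append(state.n_food)

    # -- tabular exports ------------------------------------------------
    def snapshot_table(self) -> pd.DataFrame:
        """Long-format table (step, t, id, x, y, vx, vy, m) over all snapshots."""
        frames = [
            pd.DataFrame({
                "step": s.step, "t": s.t, "id": s.ids,
                "x": s.r[:, 0], "y": s.r[:, 1],
                "vx": s.v[:, 0], "vy": s.v[:, 1], "m": s.m,
            })
            for s in self.snapshots if s.n > 0
        ]
        if not frames:
            return pd.DataFrame(columns=["step", "t", "id", "x", "y", "vx", "vy", "m"])
        return pd.concat(frames, ignore_index=True)

    def counters_table(self) -> pd.DataFrame:
        """Counter series (t, N, N_c1, N_c2, N_c3, n_died, n_born, n_food).

        n_born is cumulative recruitment; the current population N is exported
        alongside it so either reading of a "survived" count is available.
        """
        cls = np.array(self.rec_classes) if self.rec_classes else np.zeros((0, 3), dtype=int)
        return pd.DataFrame({
            "step": self.rec_steps, "t": self.rec_t, "N": self.rec_n,
            "N_c1": cls[:, 0] if len(cls) else [], "N_c2": cls[:, 1] if len(cls) else [],
            "N_c3": cls[:, 2] if len(cls) else [],
            "n_died": self.rec_died, "n_born": self.rec_born, "n_food": self.rec_nfood,
        })

    def save(self, out_dir: str | Path) -> None:
        """Write snapshots, counters, config and run log as plain text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.snapshot_table().to_csv(out / "snapshots.csv", index=False)
        self.counters_table().to_csv(out / "counters.csv", index=False)
        (out / "config.txt").write_text(params_to_config(self.params))
        log = {
            "seed": self.params.seed,
            "params_hash": params_hash(self.params),
            "n_snapshots": len(self.snapshots),
            "final_t": self.rec_t[-1] if self.rec_t else 0.0,
            "final_N": self.rec_n[-1] if self.rec_n else 0,
            "extinction_times": self.extinctions,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def run(p: SimulationParams, n_steps: int, record_every: int = 100,
        initial_state: SimulationState | None = None,
        check_every: int = 0) -> RunRecord:
    """Integrate ``n_steps`` steps, recording every ``record_every`` steps.

    The initial state is always recorded.  Extinction (N reaching 0) is
    recorded as an event, not an error: food keeps depositing and recruitment
    keeps trying, so the population can re-establish.  ``check_every > 0``
    asserts the population-bookkeeping invariant at that cadence.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1 (got {n_steps})")
    validate_params(p)
    state = init_state(p) if initial_state is None else initial_state
    rec = RunRecord(params=p)
    rec.record(0, state)
    alive = state.n > 0
    for i in range(1, n_steps + 1):
        step(state, p)
        if alive and state.n == 0:
            rec.extinctions.append(state.t)
        alive = state.n > 0
        if i % record_every == 0:
            rec.record(i, state)
        if check_every and i % check_every == 0:
            check_bookkeeping(state)
    rec.final_state = state
    return rec
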