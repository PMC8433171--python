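"""Population statistics: nearest-neighbor distances, mass/volume histograms,
velocity-vs-mass curves, time-volume maps, and 1D density profiles.

Histogram accumulators keep both the *instant* counts of the last folded
snapshot and the *long-run* counts summed over every snapshot folded so far,
mirroring the instant (thin) vs accumulated (thick) curves used to
characterize a run.  Body volume is taken proportional to mass with unit
density, so mass histograms double as volume histograms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .core import SimulationParams, SimulationState
from .demography import classify_size
from .dynamics import RunRecord
from .forces import equilibrium_distance

__all__ = [
    "nearest_neighbor_distances",
    "HistogramAccumulator",
    "default_nnd_edges",
    "default_mass_edges",
    "nnd_histogram",
    "mass_histogram",
    "velocity_vs_mass",
    "speed_mass_spearman",
    "time_volume_map",
    "density_profiles",
]

log = logging.getLogger(__name__)


def nearest_neighbor_distances(positions: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to the closest other point.

    Uses a k-d tree (k=2 query; the first neighbor of a point is itself).
    Requires at least two points.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError(f"need >= 2 points for nearest-neighbor distances (got shape {pos.shape})")
    d, _ = cKDTree(pos).query(pos, k=2)
    return d[:, 1]


@dataclass
class HistogramAccumulator:
    """Fixed-bin histogram with instant and long-run counts.

    Observations falling outside the bin range go to an overflow counter and
    are logged, never silently dropped: instant + overflow always equals the
    number of observations folded.
    """

    edges: np.ndarray
    instant: np.ndarray = field(init=False)
    long_run: np.ndarray = field(init=False)
    instant_overflow: int = field(init=False, default=0)
    overflow: int = field(init=False, default=0)
    n_snapshots: int = field(init=False, default=0)
    n_observations: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be a 1D strictly increasing array of length >= 2")
        self.instant = np.zeros(self.edges.size - 1)
        self.long_run = np.zeros(self.edges.size - 1)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def fold(self, values: np.ndarray) -> "HistogramAccumulator":
        """Replace the instant counts with this sample; add to the long run."""
        values = np.asarray(values, dtype=float).ravel()
        counts, _ = np.histogram(values, bins=self.edges)
        n_out = values.size - int(counts.sum())
        if n_out:
            log.warning("%d observation(s) outside histogram range [%g, %g]",
                        n_out, self.edges[0], self.edges[-1])
        self.instant = counts.astype(float)
        self.instant_overflow = n_out
        self.long_run += counts
        self.overflow += n_out
        self.n_snapshots += 1
        self.n_observations += values.size
        return self

    def mode_center(self, which: str = "long_run") -> float:
        """Center of the most populated bin (ties -> lowest bin)."""
        counts = getattr(self, which)
        return float(self.centers[int(np.argmax(counts))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "left": self.edges[:-1], "right": self.edges[1:],
            "instant": self.instant, "long_run": self.long_run,
        })


def default_nnd_edges(p: SimulationParams) -> np.ndarray:
    """NND bins of width R_min/10 from 0 to the arena diagonal."""
    w = equilibrium_distance(p.m_s, p) / 10.0
    diag = float(np.hypot(p.Lx, p.Ly))
    return np.arange(0.0, diag + w, w)


def default_mass_edges(p: SimulationParams) -> np.ndarray:
    """Mass bins of width (m_max - m_min)/40 spanning (0, m_max]."""
    w = (p.m_max - p.m_min) / 40.0
    return np.arange(0.0, p.m_max + w, w)


def nnd_histogram(state: SimulationState, acc: HistogramAccumulator) -> HistogramAccumulator:
    """Fold the current nearest-neighbor distances into the accumulator."""
    return acc.fold(nearest_neighbor_distances(state.r))


def mass_histogram(state: SimulationState, acc: HistogramAccumulator) -> HistogramAccumulator:
    """Fold the current masses (== volumes, unit density) into the accumulator."""
    return acc.fold(state.m)


def velocity_vs_mass(masses: np.ndarray, speeds: np.ndarray, mass_edges: np.ndarray) -> pd.DataFrame:
    """Mean speed per mass bin; empty bins carry NaN (missing, not zero)."""
    masses = np.asarray(masses, dtype=float).ravel()
    speeds = np.asarray(speeds, dtype=float).ravel()
    if masses.size == 0:
        raise ValueError("need at least one observation")
    idx = np.digitize(masses, mass_edges) - 1
    nbin = len(mass_edges) - 1
    ok = (idx >= 0) & (idx < nbin)
    counts = np.bincount(idx[ok], minlength=nbin)
    sums = np.bincount(idx[ok], weights=speeds[ok], minlength=nbin)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "m_center": 0.5 * (mass_edges[:-1] + mass_edges[1:]),
        "mean_speed": mean,
        "count": counts,
    })


def _pool_snapshots(snapshots) -> tuple[np.ndarray, np.ndarray]:
    masses = np.concatenate([s.m for s in snapshots if s.n > 0]) if snapshots else np.empty(0)
    speeds = np.concatenate([s.speed for s in snapshots if s.n > 0]) if snapshots else np.empty(0)
    return masses, speeds


def speed_mass_spearman(snapshots, mass_edges: np.ndarray, min_count: int = 5) -> float:
    """Spearman rank correlation between mass-bin center and binned mean speed.

    Pools all given snapshots; bins with fewer than ``min_count`` pooled
    observations are excluded as unreliable.
    """
    masses, speeds = _pool_snapshots(snapshots)
    curve = velocity_vs_mass(masses, speeds, mass_edges)
    sel = curve["count"] >= min_count
    if sel.sum() < 3:
        raise ValueError("too few populated mass bins for a rank correlation")
    rho, _ = spearmanr(curve.loc[sel, "m_center"], curve.loc[sel, "mean_speed"])
    return float(rho)


def time_volume_map(record: RunRecord, mass_edges: np.ndarray,
                    n_time_bins: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-snapshot mass (volume) histograms into a (time x mass) map.

    With ``n_time_bins`` given, consecutive snapshots are averaged into that
    many time bins; otherwise one row per snapshot.  Returns
    (map, time_bin_centers, mass_edges); each unaveraged row sums to the
    population size at that snapshot.
    """
    snaps = record.snapshots
    if not snaps:
        raise ValueError("record holds no snapshots")
    rows = np.stack([np.histogram(s.m, bins=mass_edges)[0] for s in snaps]).astype(float)
    times = np.array([s.t for s in snaps])
    if n_time_bins is None or n_time_bins >= len(snaps):
        return rows, times, np.asarray(mass_edges, dtype=float)
    groups = np.array_split(np.arange(len(snaps)), n_time_bins)
    binned = np.stack([rows[g].mean(axis=0) for g in groups])
    t_centers = np.array([times[g].mean() for g in groups])
    return binned, t_centers, np.asarray(mass_edges, dtype=float)


def density_profiles(record: RunRecord, n_bins_x: int = 30) -> pd.DataFrame:
    """Time-averaged 1D densities along x (the axis facing the dangerous wall).

    Returns per-bin mean counts of food portions, of all animals, and of each
    size class, averaged over every snapshot in the record.
    """
    p = record.params
    snaps = record.snapshots
    if not snaps:
        raise ValueError("record holds no snapshots")
    edges = np.linspace(0.0, p.Lx, n_bins_x + 1)
    total = np.zeros(n_bins_x)
    per_class = np.zeros((3, n_bins_x))
    food = np.zeros(n_bins_x)
    for s in snaps:
        if s.n > 0:
            total += np.histogram(s.r[:, 0], bins=edges)[0]
            codes = classify_size(s.m, p)
            for c in range(3):
                per_class[c] += np.histogram(s.r[codes == c, 0], bins=edges)[0]
        if s.food_r.shape[0] > 0:
            food += np.histogram(s.food_r[:, 0], bins=edges)[0]
    nsnap = len(snaps)
    return pd.DataFrame({
        "x_center": 0.5 * (edges[:-1] + edges[1:]),
        "food": food / nsnap,
        "animals": total / nsnap,
        "small": per_class[0] / nsnap,
        "medium": per_class[1] / nsnap,
        "large": per_class[2] / nsnap,
    })
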