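"""Field-video reduction: perspective camera-to-ground transform, body-volume
estimation, empirical histograms, and the two-sample KS comparison — plus a
synthetic scene generator so the whole pipeline is testable without video.

Geometry: a camera at height ``h`` looks down at the water surface, its
optical axis tilted by ``alpha`` from the ground plane's normal direction
convention used here (alpha is the angle between the ground plane and the
camera-plane normal).  A pixel (x_c, y_c) on the sensor of resolution
(x_cm, y_cm) with horizontal view angle ``beta`` maps to ground coordinates

    y_r = h * [ cot(alpha + atan( (2 y_c - y_cm)/x_cm * tan(beta/2) )) - cot(alpha) ],
    x_r = (2 x_c - x_cm)/x_cm * h * sqrt(1 + (y_r/h + cot(alpha))^2) * tan(beta/2),

with the image center mapping to the field origin.  Pixels whose ray passes
above the horizon have no ground intersection and are rejected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

__all__ = [
    "CameraParams",
    "camera_to_field",
    "field_to_camera",
    "pixel_scale",
    "ellipsoid_volume",
    "ks_two_sample",
    "synthesize_scene",
    "reduce_detections",
    "wave_speed_consistency",
]

DETECTION_COLUMNS = ("frame", "x_c", "y_c", "len_px", "wid_px")


@dataclass(frozen=True)
class CameraParams:
    """Perspective-camera description for the ground-plane transform.

    tilt: angle between ground plane and the camera-plane normal (rad).
    hfov: horizontal view angle (rad).  h: camera height over ground.
    x_cm, y_cm: horizontal and vertical sensor resolution in pixels.
    """

    tilt: float
    hfov: float
    h: float
    x_cm: int
    y_cm: int

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt < math.pi / 2:
            raise ValueError(f"tilt must lie in (0, pi/2) (got {self.tilt})")
        if not 0.0 < self.hfov < math.pi:
            raise ValueError(f"hfov must lie in (0, pi) (got {self.hfov})")
        if self.h <= 0:
            raise ValueError(f"camera height must be positive (got {self.h})")
        if int(self.x_cm) != self.x_cm or int(self.y_cm) != self.y_cm or self.x_cm <= 0 or self.y_cm <= 0:
            raise ValueError(f"resolutions must be positive integers (got {self.x_cm} x {self.y_cm})")


def camera_to_field(x_c, y_c, cam: CameraParams):
    """Map pixel coordinates to ground-plane field coordinates (x_r, y_r).

    Raises ValueError if any input pixel's line of sight misses the ground
    (at or above the horizon); the message identifies the offending index.
    """
    x_c = np.asarray(x_c, dtype=float)
    y_c = np.asarray(y_c, dtype=float)
    cot_a = 1.0 / math.tan(cam.tilt)
    t_half = math.tan(cam.hfov / 2.0)
    gamma = np.arctan((2.0 * y_c - cam.y_cm) / cam.x_cm * t_half)
    ang = cam.tilt + gamma
    bad = np.asarray(ang <= 0.0) | np.asarray(ang >= math.pi)
    if bad.any():
        idx = np.argwhere(np.atleast_1d(bad)).ravel()[0]
        raise ValueError(f"pixel row {idx}: line of sight does not reach the ground (above horizon)")
    y_r = cam.h * (1.0 / np.tan(ang) - cot_a)
    slant = np.sqrt(1.0 + (y_r / cam.h + cot_a) ** 2)
    x_r = (2.0 * x_c - cam.x_cm) / cam.x_cm * cam.h * slant * t_half
    if np.any(~np.isfinite(y_r)) or np.any(~np.isfinite(x_r)):
        idx = np.argwhere(~(np.isfinite(np.atleast_1d(y_r)) & np.isfinite(np.atleast_1d(x_r)))).ravel()[0]
        raise ValueError(f"pixel row {idx}: transform produced a non-finite field coordinate")
    return x_r, y_r


def field_to_camera(x_r, y_r, cam: CameraParams):
    """Inverse transform: ground point -> pixel coordinates.

    A point is imageable if its viewing ray lies below the horizon, i.e.
    y_r/h + cot(tilt) > 0; anything else raises ValueError.
    """
    x_r = np.asarray(x_r, dtype=float)
    y_r = np.asarray(y_r, dtype=float)
    cot_a = 1.0 / math.tan(cam.tilt)
    t_half = math.tan(cam.hfov / 2.0)
    c = y_r / cam.h + cot_a
    bad = np.asarray(c <= 0.0)
    if bad.any():
        idx = np.argwhere(np.atleast_1d(bad)).ravel()[0]
        raise ValueError(f"field point row {idx}: not imageable (at or behind the horizon)")
    # cot(tilt + gamma) = c  with  tilt + gamma in (0, pi/2]
    gamma = np.arctan(1.0 / c) - cam.tilt
    y_c = 0.5 * (cam.y_cm + cam.x_cm * np.tan(gamma) / t_half)
    slant = np.sqrt(1.0 + c**2)
    x_c = 0.5 * (cam.x_cm + cam.x_cm * x_r / (cam.h * slant * t_half))
    return x_c, y_c


def pixel_scale(x_c, y_c, cam: CameraParams, delta: float = 1e-3):
    """Local ground distance per horizontal pixel at the given pixel(s).

    Central finite difference of the transform along x_c; used to convert
    measured pixel lengths into field lengths (and back when synthesizing).
    """
    x_c = np.asarray(x_c, dtype=float)
    y_c = np.asarray(y_c, dtype=float)
    xa, _ = camera_to_field(x_c - delta, y_c, cam)
    xb, _ = camera_to_field(x_c + delta, y_c, cam)
    return np.abs(xb - xa) / (2.0 * delta)


def ellipsoid_volume(length, width, thickness_factor: float = 1.0):
    """Two-axis ellipsoid body volume V = factor * (pi/6) * L * W^2.

    Semi-axes L/2, W/2, W/2: body thickness is taken equal to body width;
    ``thickness_factor`` absorbs the unknown thickness-to-width ratio.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("ellipsoid axes must be positive")
    if np.any(length < width):
        raise ValueError("body length must be >= body width")
    return thickness_factor * (math.pi / 6.0) * length * width**2


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_a - ECDF_b| evaluated exactly at the pooled sample points;
    p-value from the asymptotic KS distribution at sqrt(n_eff) * D with
    n_eff = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(math.sqrt(n_eff) * d))
    return d, p


def synthesize_scene(positions, lengths, widths, cam: CameraParams,
                     sigma_px: float = 0.0, seed: int | np.random.Generator = 0,
                     frame: int = 0) -> pd.DataFrame:
    """Project ground-truth animals into a synthetic detection table.

    Synthetic stand-in for a processed video frame: each animal's field
    position is pushed through the inverse camera transform, its body axes
    are converted to pixels with the local scale, and Gaussian pixel noise
    (sigma_px) is added to the centroid.  Output columns:
    (frame, x_c, y_c, len_px, wid_px).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.asarray(positions, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    widths = np.asarray(widths, dtype=float)
    x_c, y_c = field_to_camera(pos[:, 0], pos[:, 1], cam)
    scale = pixel_scale(x_c, y_c, cam)
    if sigma_px > 0:
        x_c = x_c + rng.normal(0.0, sigma_px, size=x_c.shape)
        y_c = y_c + rng.normal(0.0, sigma_px, size=y_c.shape)
    return pd.DataFrame({
        "frame": frame,
        "x_c": x_c,
        "y_c": y_c,
        "len_px": lengths / scale,
        "wid_px": widths / scale,
    })


def reduce_detections(table: pd.DataFrame, cam: CameraParams,
                      thickness_factor: float = 1.0) -> pd.DataFrame:
    """Reduce a detection table to field coordinates and body volumes.

    Input columns (frame, x_c, y_c, len_px, wid_px); output
    (frame, x_r, y_r, length, width, volume) with lengths in field units and
    the two-axis ellipsoid volume.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"detection table lacks column(s): {', '.join(missing)}")
    x_r, y_r = camera_to_field(table["x_c"].to_numpy(), table["y_c"].to_numpy(), cam)
    scale = pixel_scale(table["x_c"].to_numpy(), table["y_c"].to_numpy(), cam)
    length = table["len_px"].to_numpy() * scale
    width = table["wid_px"].to_numpy() * scale
    return pd.DataFrame({
        "frame": table["frame"].to_numpy(),
        "x_r": x_r,
        "y_r": y_r,
        "length": length,
        "width": width,
        "volume": ellipsoid_volume(length, width, thickness_factor),
    })


def wave_speed_consistency(y_c_start: float, y_c_end: float, x_c: float,
                           elapsed_s: float, cam: CameraParams,
                           expected_speed: float = 0.24) -> tuple[float, float]:
    """Check a user-supplied calibration against the known surface-wave speed.

    A circular surface wavefront observed at pixel rows y_c_start and
    y_c_end (same column x_c) a time ``elapsed_s`` apart implies a ground
    speed; returns (measured_speed, relative_deviation from expected, which
    is 0.24 m/s for water surface waves).  This is a consistency checker,
    not a fitter.
    """
    if elapsed_s <= 0:
        raise ValueError(f"elapsed time must be positive (got {elapsed_s})")
    _, y0 = camera_to_field(x_c, y_c_start, cam)
    _, y1 = camera_to_field(x_c, y_c_end, cam)
    speed = abs(float(y1) - float(y0)) / elapsed_s
    return speed, abs(speed - expected_speed) / expected_speed
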