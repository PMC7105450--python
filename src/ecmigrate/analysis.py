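"""Migration statistics computed from trajectories.

All readouts are pure functions of a :class:`~ecmigrate.trajectory.Trajectory`
(no re-simulation): angular distributions of net cell displacement, mean
path-length migration speed, axial density profiles and their minimum, and
entrapment counts for recirculation zones.

Angles are measured in the substrate (x-z) plane with 180° pointing
downstream (+x); wall-normal motion is ignored in angle statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "AngularHistogram",
    "DensityProfile",
    "angular_distribution",
    "mean_migration_speed",
    "axial_distribution",
    "density_minimum_location",
    "entrapment_count",
]

ANGULAR_BIN_WIDTH = 15.0  # degrees, 24 bins


@dataclass
class AngularHistogram:
    """Percentage of cells per displacement-angle bin (0-360°, 180° = downstream)."""

    bin_edges: np.ndarray       # degrees, length n_bins + 1
    percentage: np.ndarray      # sums to 100 over included cells
    counts: np.ndarray          # raw cell counts per bin
    n_excluded: int = 0         # cells with (near-)zero displacement

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.percentage = np.asarray(self.percentage, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.sum() and abs(self.percentage.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DensityProfile:
    """Normalised axial distribution of cells (integrates to 1)."""

    bin_edges: np.ndarray       # mm
    density: np.ndarray         # per mm

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        widths = np.diff(self.bin_edges)
        total = float((self.density * widths).sum())
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("density must integrate to 1")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def displacement_angles(traj: Trajectory, window: tuple[float, float],
                        min_displacement: float = 1e-9):
    """Net in-plane displacement angle per mobile cell over the window.

    Returns (angles_deg, included_mask over mobile cells).  The angle is
    ``(atan2(dz, dx) + 180°) mod 360`` so pure downstream (+x) motion maps
    to 180°.
    """
    sub = traj.window(*window)
    d = sub.positions[-1] - sub.positions[0]
    d = d[traj.mobile]
    planar = np.hypot(d[:, 0], d[:, 2])
    included = planar >= min_displacement
    ang = (np.degrees(np.arctan2(d[included, 2], d[included, 0])) + 180.0) % 360.0
    return ang, included


def angular_distribution(traj: Trajectory, window: tuple[float, float],
                         origin_rule: dict | None = None,
                         bin_width: float = ANGULAR_BIN_WIDTH) -> AngularHistogram:
    """Histogram of net displacement angles over ``window`` (24 x 15° bins).

    ``origin_rule`` optionally restricts the analysis the way the ridged-
    channel readout does: ``{"downstream_of": x_mm}`` keeps only cells whose
    window-start position lies downstream of that coordinate (conventionally
    50 µm past the ridge's trailing face); cells upstream are dropped before
    binning.
    """
    sub = traj.window(*window)
    mobile_pos0 = sub.positions[0][traj.mobile]
    keep = np.ones(len(mobile_pos0), dtype=bool)
    if origin_rule and "downstream_of" in origin_rule:
        keep = mobile_pos0[:, 0] >= origin_rule["downstream_of"]

    d = (sub.positions[-1] - sub.positions[0])[traj.mobile][keep]
    planar = np.hypot(d[:, 0], d[:, 2])
    moved = planar >= 1e-9
    ang = (np.degrees(np.arctan2(d[moved, 2], d[moved, 0])) + 180.0) % 360.0

    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(ang, bins=edges)
    total = counts.sum()
    pct = counts * (100.0 / total) if total else np.zeros(n_bins)
    return AngularHistogram(edges, pct, counts, n_excluded=int((~moved).sum()))


def mean_migration_speed(traj: Trajectory,
                         window: tuple[float, float]) -> tuple[float, float]:
    """Mean sampled path-length speed of mobile cells over the window, in µm/h.

    Speed per cell = polyline length of its sampled track / window duration;
    returns (mean, standard error) over mobile cells.  Positions are mm and
    times hours, so the conversion factor is 1000.
    """
    sub = traj.window(*window)
    if sub.n_frames < 2:
        raise ValueError("window must contain at least two frames")
    duration = sub.times[-1] - sub.times[0]
    steps = np.diff(sub.positions, axis=0)
    path = np.linalg.norm(steps, axis=2).sum(axis=0)[traj.mobile]
    speeds = path / duration * 1000.0
    mean = float(speeds.mean())
    se = float(speeds.std(ddof=1) / math.sqrt(len(speeds))) if len(speeds) > 1 else 0.0
    return mean, se


def axial_distribution(traj: Trajectory, at_time: float,
                       bins: float | np.ndarray = 0.06,
                       origin: float = 0.0,
                       x_range: tuple[float, float] | None = None) -> DensityProfile:
    """Normalised histogram of mobile-cell x positions at ``at_time``.

    ``origin`` shifts the coordinate (e.g. 50 µm downstream of a ridge's
    trailing face becomes x = 0).  ``bins`` is either a bin width (mm,
    default one cell spacing) or an explicit edge array in the shifted
    coordinate.
    """
    idx = int(np.argmin(np.abs(traj.times - at_time)))
    if abs(traj.times[idx] - at_time) > traj.interval + 1e-9:
        raise ValueError(f"time {at_time} h outside trajectory span")
    x = traj.positions[idx][traj.mobile, 0] - origin
    if np.isscalar(bins):
        if x_range is None:
            lo = math.floor(x.min() / bins) * bins
            hi = math.ceil(x.max() / bins) * bins
        else:
            lo, hi = x_range
        n = max(1, int(round((hi - lo) / bins)))
        edges = lo + bins * np.arange(n + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    total = counts.sum()
    density = counts / (total * widths) if total else np.zeros(len(counts))
    return DensityProfile(edges, density)


def density_minimum_location(profile: DensityProfile,
                             search_interval: tuple[float, float],
                             smooth_bins: int = 3) -> float:
    """Axial location (mm) of the minimum of the moving-average-smoothed profile.

    A centred ``smooth_bins``-bin moving average is applied first; ties go
    to the smallest x.  Raises if the search interval contains no bins or
    only empty ones.
    """
    centres = profile.bin_centres
    kernel = np.ones(smooth_bins) / smooth_bins
    pad = smooth_bins // 2
    padded = np.pad(profile.density, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    lo, hi = search_interval
    sel = (centres >= lo) & (centres <= hi)
    if not sel.any():
        raise ValueError("search interval contains no bins")
    if not np.any(profile.density[sel] > 0) and not np.any(smooth[sel] > 0):
        raise ValueError("profile is zero everywhere on the search interval")
    sub = smooth[sel]
    return float(centres[sel][int(np.argmin(sub))])


def entrapment_count(traj: Trajectory, zone: tuple[float, float],
                     window: tuple[float, float]) -> int:
    """Cells that enter the axial zone during the window and are still inside
    at the window's end."""
    sub = traj.window(*window)
    x = sub.positions[:, traj.mobile, 0]
    lo, hi = zone
    inside = (x >= lo) & (x <= hi)
    entered = (~inside[0]) & inside.any(axis=0)
    return int((entered & inside[-1]).sum())
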