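"""Moisture-content bookkeeping and drying-run assembly.

Dry-basis moisture content MC_t = (m_t - m_d)/m_d (g water per g dry solids),
moisture ratio MR_t = MC_t/MC_0, and area ratio AR_t = A_t/A_0 are the three
scalar series of a drying run. ``build_run`` runs the imaging chain over a
frame sequence, aligns the result with the weight series on the acquisition
clock, and emits one tidy :class:`DryingRun`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import DegenerateHistogramError, segment_frame

__all__ = [
    "WeightSeries",
    "DryingRun",
    "moisture_content",
    "moisture_ratio",
    "wet_to_dry_basis",
    "dry_to_wet_basis",
    "area_ratio_series",
    "build_run",
    "average_runs",
]

#: columns of a DryingRun frame, in output order
RUN_COLUMNS = ["time_min", "area_px", "AR", "mass_g", "MC", "MR",
               "threshold_k", "n_particles"]


@dataclass
class WeightSeries:
    """Mass samples over a drying run.

    times are minutes from drying start (strictly increasing), masses in
    grams, ``dry_mass`` the bone-dry solids mass m_d in grams.
    """

    times: np.ndarray
    masses: np.ndarray
    dry_mass: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.times.shape != self.masses.shape or self.times.ndim != 1:
            raise ValueError("times and masses must be 1-D arrays of equal length")
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.dry_mass <= 0:
            raise ValueError("dry mass must be positive")

    @classmethod
    def from_csv(cls, path, dry_mass: float) -> "WeightSeries":
        """Read a ``time_min,mass_g`` CSV."""
        df = pd.read_csv(path)
        missing = {"time_min", "mass_g"} - set(df.columns)
        if missing:
            raise ValueError(f"weight CSV missing columns {sorted(missing)}")
        return cls(df["time_min"].to_numpy(), df["mass_g"].to_numpy(), dry_mass)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times, "mass_g": self.masses}).to_csv(path, index=False)


def moisture_content(m_t, m_d: float):
    """Dry-basis moisture content MC = (m_t - m_d)/m_d in g/g."""
    m_t = np.asarray(m_t, dtype=np.float64)
    if m_d <= 0:
        raise ValueError("dry mass must be positive")
    if np.any(m_t < m_d):
        raise ValueError("wet mass below dry mass: negative moisture is impossible")
    out = (m_t - m_d) / m_d
    return float(out) if out.ndim == 0 else out


def moisture_ratio(mc_t, mc_0: float):
    """Moisture ratio MR = MC_t/MC_0 (1 at the start of drying)."""
    if mc_0 <= 0:
        raise ValueError("initial moisture content must be positive")
    out = np.asarray(mc_t, dtype=np.float64) / mc_0
    return float(out) if out.ndim == 0 else out


def wet_to_dry_basis(w):
    """Convert a wet-basis moisture fraction w to dry basis: w/(1-w)."""
    w = np.asarray(w, dtype=np.float64)
    if np.any((w < 0) | (w >= 1)):
        raise ValueError("wet-basis fraction must lie in [0, 1)")
    out = w / (1.0 - w)
    return float(out) if out.ndim == 0 else out


def dry_to_wet_basis(d):
    """Inverse of :func:`wet_to_dry_basis`: d/(1+d)."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("dry-basis moisture content must be non-negative")
    out = d / (1.0 + d)
    return float(out) if out.ndim == 0 else out


def area_ratio_series(areas: Sequence[float]) -> np.ndarray:
    """AR_t = A_t/A_0 with AR_0 exactly 1; NaN areas propagate as NaN."""
    a = np.asarray(areas, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty area series")
    if not np.isfinite(a[0]) or a[0] <= 0:
        raise ValueError("first-frame area missing or zero: cannot normalize")
    ar = a / a[0]
    ar[0] = 1.0
    return ar


@dataclass
class DryingRun:
    """Aligned per-frame record of one drying experiment.

    ``data`` carries time_min, area_px, AR, mass_g, MC, MR plus the per-frame
    segmentation diagnostics threshold_k and n_particles. AR and MR are both
    exactly 1 in the first row by construction.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(RUN_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"run missing columns {sorted(missing)}")
        df = self.data[RUN_COLUMNS].reset_index(drop=True)
        for col in RUN_COLUMNS:
            df[col] = df[col].astype(np.int64 if col == "n_particles" else np.float64)
        self.data = df

    @property
    def times(self):
        return self.data["time_min"].to_numpy()

    @property
    def ar(self):
        return self.data["AR"].to_numpy()

    @property
    def mr(self):
        return self.data["MR"].to_numpy()

    def modeling_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(AR, MR) rows usable for regression: both finite."""
        ar, mr = self.ar, self.mr
        ok = np.isfinite(ar) & np.isfinite(mr)
        return ar[ok], mr[ok]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "DryingRun":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.data)


def _nearest_mass(t: float, weights: WeightSeries, tol: float) -> float:
    i = int(np.argmin(np.abs(weights.times - t)))
    if abs(weights.times[i] - t) <= tol:
        return float(weights.masses[i])
    return np.nan


def build_run(frames: Iterable, times: Sequence[float], weights: WeightSeries,
              *, min_pixels: int = 200, strict: bool = False) -> DryingRun:
    """Assemble a :class:`DryingRun` from frames and a weight series.

    Parameters
    ----------
    frames
        Iterable of RGB arrays or image file paths, time-ordered.
    times
        Frame acquisition times in minutes, same length as ``frames``.
    weights
        Mass series; matched to each frame by nearest time within half the
        median frame interval. Unmatched frames carry NaN mass/MC/MR.
    min_pixels
        Particle size filter passed to the imaging chain.
    strict
        If True, a wet mass below the dry mass raises; by default it is
        clipped to zero moisture with a warning (scale noise near the
        endpoint can push m_t marginally under m_d).

    An unsegmentable first frame aborts (A_0 is the normalizer); later
    unsegmentable or unreadable frames are recorded as missing.
    """
    times = np.asarray(times, dtype=np.float64)
    frames = list(frames)
    if len(frames) != times.size:
        raise ValueError("frames and times must have equal length")
    if times.size == 0:
        raise ValueError("empty frame sequence")

    areas = np.full(times.size, np.nan)
    thresholds = np.full(times.size, np.nan)
    n_particles = np.zeros(times.size, dtype=np.int64)
    for i, frame in enumerate(frames):
        try:
            img = _load_frame(frame)
            seg = segment_frame(img, min_pixels=min_pixels)
        except (DegenerateHistogramError, OSError, ValueError) as exc:
            if i == 0:
                raise RuntimeError(f"first frame unsegmentable: {exc}") from exc
            warnings.warn(f"frame {i} (t={times[i]:g} min) unsegmentable: {exc}")
            continue
        if seg.n_particles == 0:
            # no particle survived filtering: missing, not zero
            if i == 0:
                raise RuntimeError("first frame has no particle above min_pixels")
            thresholds[i] = seg.threshold.k
            continue
        areas[i] = seg.area
        thresholds[i] = seg.threshold.k
        n_particles[i] = seg.n_particles

    ar = area_ratio_series(areas)

    interval = float(np.median(np.diff(times))) if times.size > 1 else np.inf
    tol = interval / 2.0
    masses = np.array([_nearest_mass(t, weights, tol) for t in times])

    m_d = weights.dry_mass
    if np.any(masses[np.isfinite(masses)] < m_d):
        if strict:
            raise ValueError("wet mass below dry mass in weight series")
        warnings.warn("wet mass below dry mass; clipping moisture content at 0")
        masses = np.where(np.isfinite(masses), np.maximum(masses, m_d), masses)

    with np.errstate(invalid="ignore"):
        mc = (masses - m_d) / m_d
    if not np.isfinite(mc[0]) or mc[0] <= 0:
        raise ValueError("initial moisture content missing or non-positive")
    mr = mc / mc[0]
    mr[0] = 1.0

    return DryingRun(pd.DataFrame({
        "time_min": times, "area_px": areas, "AR": ar, "mass_g": masses,
        "MC": mc, "MR": mr, "threshold_k": thresholds, "n_particles": n_particles,
    }))


def _load_frame(frame):
    if isinstance(frame, (str, Path)):
        import imageio.v3 as iio
        arr = iio.imread(frame)
        if arr.ndim == 3 and arr.shape[-1] == 4:
            arr = arr[..., :3]
        return arr
    return frame


def average_runs(runs: Sequence[DryingRun]) -> DryingRun:
    """Arithmetic mean of replicate runs sharing one time grid.

    Replicates are averaged per time point; diagnostics (threshold_k,
    n_particles) are averaged too, n_particles rounded.
    """
    if not runs:
        raise ValueError("no runs to average")
    t0 = runs[0].times
    for r in runs[1:]:
        if len(r) != len(runs[0]) or not np.allclose(r.times, t0):
            raise ValueError("replicate runs must share an identical time grid")
    stacked = np.stack([r.data[RUN_COLUMNS].to_numpy(dtype=np.float64) for r in runs])
    mean = np.nanmean(stacked, axis=0)
    df = pd.DataFrame(mean, columns=RUN_COLUMNS)
    df["time_min"] = t0
    df["n_particles"] = np.round(df["n_particles"]).astype(np.int64)
    return DryingRun(df)
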