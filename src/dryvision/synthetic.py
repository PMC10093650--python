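"""Synthetic drying runs: rendered frame sequences plus matched weight series.

Emulates the imaging conditions the segmentation chain assumes — bright
circular samples on a dark cloth background with high contrast, transient
dark bubbles strictly interior to the samples, and small bright dust specks —
driven by a parametric drying law so ground truth is available for recovery
tests.

The default law is Page-type, MR(t) = exp(-k·tⁿ), the standard monotone
moisture-ratio curve in drying kinetics, with a linear shrinkage link
AR = 1 - c·(1 - MR). Any user MR(t) callable is accepted. The matched mass
series inverts the moisture bookkeeping: m_t = m_d·(1 + MC0·MR(t)) + noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .drying import WeightSeries, build_run, DryingRun

__all__ = [
    "SceneSpec",
    "DryingLaw",
    "ExperimentData",
    "render_sequence",
    "generate_weights",
    "make_experiment_pair",
    "STOP_MOISTURE_RATIO",
]

#: drying stops at dry-basis MC 0.176 from an initial 9.87 g/g
STOP_MOISTURE_RATIO = 0.176 / 9.87


@dataclass
class SceneSpec:
    """Geometry and photometry of the rendered scene.

    Disks are (row, col, radius_px) at t=0 and must lie fully inside the
    frame without overlapping. Foreground/background levels are separated by
    well over 80 gray levels so histogram thresholding is well-posed. Dust
    specks are small bright clusters fixed on the background cloth; bubbles
    are transient dark circles strictly interior to disks.
    """

    height: int = 400
    width: int = 400
    disks: tuple = ((120.0, 120.0, 70.0), (280.0, 270.0, 55.0))
    fg_level: float = 200.0
    bg_level: float = 30.0
    gray_jitter: float = 6.0
    dust_count: int = 30
    dust_radius: tuple = (1.0, 2.5)
    dust_level: float = 180.0
    bubble_rate: float = 0.3          # events per disk per frame (Poisson)
    bubble_radius: tuple = (3.0, 8.0)
    bubble_lifetime: tuple = (2, 6)   # frames, inclusive
    bubble_level: float = 45.0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")
        if self.fg_level - self.bg_level < 80:
            raise ValueError("foreground/background separation below 80 gray levels")
        disks = np.asarray(self.disks, dtype=np.float64)
        for cy, cx, r in disks:
            if r <= 0:
                raise ValueError("disk radius must be positive")
            if cy - r < 0 or cx - r < 0 or cy + r >= self.height or cx + r >= self.width:
                raise ValueError("disk leaves the frame at t=0")
        for i in range(len(disks)):
            for j in range(i + 1, len(disks)):
                d = np.hypot(disks[i, 0] - disks[j, 0], disks[i, 1] - disks[j, 1])
                if d <= disks[i, 2] + disks[j, 2]:
                    raise ValueError(f"disks {i} and {j} overlap")


@dataclass
class DryingLaw:
    """Parametric ground truth linking time, moisture and shrinkage.

    MR(t) = exp(-k·tⁿ) (Page law) unless ``mr_func`` overrides it;
    AR(t) = 1 - c·(1 - MR(t)) with c in (0, 1] so area stays positive.
    Mass parameters invert the moisture equations; ``sigma_mass`` is the
    scale's Gaussian noise in grams (default 0.5% of the initial mass).
    """

    page_k: float = 0.068
    page_n: float = 1.2
    shrink_c: float = 0.6
    dry_mass: float = 6.0
    mc0: float = 9.87
    sigma_mass: float = field(default=None)  # type: ignore[assignment]
    sigma_area: float = 0.0                  # relative radius jitter
    mr_func: Callable | None = None

    def __post_init__(self):
        if not 0 <= self.shrink_c <= 1:
            raise ValueError("shrinkage link c must lie in [0, 1]")
        if self.dry_mass <= 0 or self.mc0 <= 0:
            raise ValueError("dry mass and initial MC must be positive")
        if self.sigma_mass is None:
            self.sigma_mass = 0.005 * self.initial_mass

    @property
    def initial_mass(self) -> float:
        return self.dry_mass * (1.0 + self.mc0)

    def mr(self, t):
        """Moisture ratio at time t (minutes)."""
        t = np.asarray(t, dtype=np.float64)
        if self.mr_func is not None:
            out = np.asarray(self.mr_func(t), dtype=np.float64)
        else:
            out = np.exp(-self.page_k * np.power(t, self.page_n))
        return float(out) if out.ndim == 0 else out

    def ar(self, t):
        """Area ratio at time t via the linear shrinkage link."""
        out = 1.0 - self.shrink_c * (1.0 - self.mr(t))
        return float(out) if np.ndim(out) == 0 else out

    def default_times(self, step: float = 0.5,
                      stop_ratio: float = STOP_MOISTURE_RATIO) -> np.ndarray:
        """Acquisition grid: every ``step`` minutes until MR <= stop_ratio."""
        times = [0.0]
        t = step
        while self.mr(t) > stop_ratio:
            times.append(t)
            t += step
            if t > 1e5:
                raise RuntimeError("drying law never reaches the stopping ratio")
        times.append(t)
        return np.asarray(times)


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


@dataclass
class _Bubble:
    disk: int
    start: int
    end: int          # exclusive frame index
    angle: float
    frac: float       # radial position as a fraction of the current disk radius
    radius: float


def _spawn_bubbles(spec: SceneSpec, n_frames: int, rng) -> list:
    bubbles = []
    for d in range(len(spec.disks)):
        n_events = rng.poisson(spec.bubble_rate * n_frames)
        for _ in range(n_events):
            start = int(rng.integers(0, n_frames))
            life = int(rng.integers(spec.bubble_lifetime[0], spec.bubble_lifetime[1] + 1))
            bubbles.append(_Bubble(
                disk=d, start=start, end=start + life,
                angle=float(rng.uniform(0, 2 * np.pi)),
                frac=float(rng.uniform(0.0, 0.7)),
                radius=float(rng.uniform(*spec.bubble_radius)),
            ))
    return bubbles


def render_sequence(spec: SceneSpec, law: DryingLaw, times: Sequence[float],
                    seed: int, *, bubbles: bool = True, dust: bool = True,
                    out_dir=None) -> tuple[list, pd.DataFrame]:
    """Render one frame per time point and tabulate exact ground truth.

    Returns ``(frames, truth)`` where frames are H×W×3 uint8 arrays and
    ``truth`` records, per frame, the exact rasterized disk pixel count with
    bubbles filled (``area_px_true``) and with bubble pixels cut out
    (``area_px_bubbled``), plus the analytic AR and MR. With ``out_dir`` set,
    writes zero-padded ``frame_NNNN.png`` files and ``truth.csv``.

    The per-frame gray jitter and the dust field are drawn from a stream
    independent of the bubble stream, so the same seed with ``bubbles=False``
    renders the identical scene minus the bubbles.
    """
    spec.validate()
    times = np.asarray(times, dtype=np.float64)
    h, w = spec.height, spec.width
    disks = np.asarray(spec.disks, dtype=np.float64)

    scene_ss, bubble_ss = np.random.SeedSequence(seed).spawn(2)
    scene_rng = np.random.default_rng(scene_ss)
    bubble_list = _spawn_bubbles(spec, times.size, np.random.default_rng(bubble_ss)) \
        if bubbles else []

    # dust cloth: fixed specks kept clear of the initial disk footprints
    dust_specks = []
    if dust:
        margin = 5.0
        attempts = 0
        while len(dust_specks) < spec.dust_count and attempts < 50 * spec.dust_count:
            attempts += 1
            dy, dx = scene_rng.uniform(0, h), scene_rng.uniform(0, w)
            dr = scene_rng.uniform(*spec.dust_radius)
            if all(np.hypot(dy - cy, dx - cx) > r0 + dr + margin for cy, cx, r0 in disks):
                dust_specks.append((dy, dx, dr))
    dust_mask = np.zeros((h, w), dtype=bool)
    for dy, dx, dr in dust_specks:
        dust_mask |= _disk_mask(h, w, dy, dx, dr)

    mr_t = law.mr(times)
    ar_t = np.atleast_1d(law.ar(times))

    frames, rows = [], []
    for i, t in enumerate(times):
        radii = disks[:, 2] * np.sqrt(ar_t[i])
        if law.sigma_area > 0:
            radii = radii * (1.0 + scene_rng.normal(0.0, law.sigma_area, size=radii.size))

        sample_mask = np.zeros((h, w), dtype=bool)
        for (cy, cx, _), r in zip(disks, radii):
            sample_mask |= _disk_mask(h, w, cy, cx, r)

        bubble_mask = np.zeros((h, w), dtype=bool)
        for b in bubble_list:
            if not (b.start <= i < b.end):
                continue
            r_disk = radii[b.disk]
            # keep a 2 px foreground rim so the hole stays completely encircled
            if b.frac * r_disk + b.radius + 2.0 > r_disk:
                continue
            cy, cx, _ = disks[b.disk]
            by = cy + b.frac * r_disk * np.sin(b.angle)
            bx = cx + b.frac * r_disk * np.cos(b.angle)
            bubble_mask |= _disk_mask(h, w, by, bx, b.radius)
        bubble_mask &= sample_mask

        gray = np.full((h, w), spec.bg_level)
        gray[dust_mask] = spec.dust_level
        gray[sample_mask] = spec.fg_level
        gray[bubble_mask] = spec.bubble_level
        gray = gray + scene_rng.normal(0.0, spec.gray_jitter, size=(h, w))
        gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
        frame = np.repeat(gray[:, :, None], 3, axis=2)
        frames.append(frame)

        rows.append({
            "time_min": t,
            "area_px_true": int(sample_mask.sum()),
            "area_px_bubbled": int((sample_mask & ~bubble_mask).sum()),
            "AR_true": ar_t[i],
            "MR_true": mr_t[i] if np.ndim(mr_t) else float(mr_t),
        })

    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio
        for i, frame in enumerate(frames):
            iio.imwrite(out_dir / f"frame_{i:04d}.png", frame)
        truth.to_csv(out_dir / "truth.csv", index=False)
    return frames, truth


def generate_weights(law: DryingLaw, times: Sequence[float], seed: int) -> WeightSeries:
    """Mass series consistent with the law: m_t = m_d·(1 + MC0·MR(t)) + noise."""
    times = np.asarray(times, dtype=np.float64)
    rng = np.random.default_rng(seed)
    backbone = law.dry_mass * (1.0 + law.mc0 * np.atleast_1d(law.mr(times)))
    noise = rng.normal(0.0, law.sigma_mass, size=times.size) if law.sigma_mass > 0 \
        else np.zeros(times.size)
    return WeightSeries(times=times, masses=backbone + noise, dry_mass=law.dry_mass)


@dataclass
class ExperimentData:
    """Inputs for one synthetic drying experiment."""

    times: np.ndarray
    frames: list
    weights: WeightSeries
    truth: pd.DataFrame
    seed: int

    def build(self, min_pixels: int = 200) -> DryingRun:
        """Run the full imaging + bookkeeping chain on the synthetic inputs."""
        return build_run(self.frames, self.times, self.weights, min_pixels=min_pixels)

    def write(self, out_dir) -> dict:
        """Write frames, weights, truth and a manifest; returns the manifest."""
        out_dir = Path(out_dir)
        frame_dir = out_dir / "frames"
        frame_dir.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio
        frame_files = []
        for i, frame in enumerate(self.frames):
            name = f"frame_{i:04d}.png"
            iio.imwrite(frame_dir / name, frame)
            frame_files.append(f"frames/{name}")
        self.weights.to_csv(out_dir / "weights.csv")
        self.truth.to_csv(out_dir / "truth.csv", index=False)
        manifest = {
            "seed": self.seed,
            "dry_mass_g": self.weights.dry_mass,
            "times_min": list(map(float, self.times)),
            "files": frame_files + ["weights.csv", "truth.csv"],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def make_experiment_pair(spec: SceneSpec | None = None, law: DryingLaw | None = None,
                         seed: int = 0, times: Sequence[float] | None = None,
                         ) -> tuple[ExperimentData, ExperimentData]:
    """Two full synthetic runs from one law with independent noise draws.

    Mirrors the protocol of training on one drying experiment and predicting
    a separate one. Deterministic in ``seed``.
    """
    spec = spec or SceneSpec()
    law = law or DryingLaw()
    times = np.asarray(times, dtype=np.float64) if times is not None \
        else law.default_times()
    children = np.random.SeedSequence(seed).spawn(2)
    out = []
    for child in children:
        render_seed, mass_seed = (int(s.generate_state(1)[0] % (2**31))
                                  for s in child.spawn(2))
        frames, truth = render_sequence(spec, law, times, seed=render_seed)
        weights = generate_weights(law, times, seed=mass_seed)
        out.append(ExperimentData(times=times, frames=frames, weights=weights,
                                  truth=truth, seed=render_seed))
    return out[0], out[1]
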