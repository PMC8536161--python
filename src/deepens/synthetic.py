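"""Synthetic benchmark-shaped datasets for the three health-data types.

The generators reproduce the *structure* of the three public benchmarks the
framework targets — a 270×13 heart-disease-style feature table with class
ratio 1.25 (normal:disease), a pneumonia-X-ray-style image set with class
ratio 0.37, and a wearable-actigraphy cohort of minute-resolution
recordings with device-off missing segments — with a planted, tunable class
signal so that learnability is controlled.  They make every pipeline stage
testable without downloading the real data; they do not attempt clinically
realistic covariance or texture.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .clu import derive_rng
from .preprocessing import MINUTES_PER_DAY, FeatureTable, ImageStack, Recording, RecordingSet

__all__ = [
    "StatisticalGenSpec",
    "ImageGenSpec",
    "SequentialGenSpec",
    "gen_statistical",
    "gen_images",
    "gen_sequential",
    "class_counts",
    "hdu_like",
    "xray_like",
    "depresjon_like",
]


def class_counts(n: int, ratio: float) -> tuple[int, int]:
    """Split n into (negative, positive) counts at ratio negative:positive,
    by largest remainder."""
    if ratio <= 0:
        raise ValueError("class_ratio must be positive")
    q_neg = n * ratio / (1.0 + ratio)
    n_neg = int(np.floor(q_neg))
    n_pos = int(np.floor(n - q_neg))
    short = n - n_neg - n_pos
    if short:
        # give the leftover to the larger fractional part; tie -> negative
        if (q_neg - n_neg) >= ((n - q_neg) - n_pos):
            n_neg += short
        else:
            n_pos += short
    if n_neg == 0 or n_pos == 0:
        raise ValueError(f"ratio {ratio} unachievable with both classes present at n={n}")
    return n_neg, n_pos


def _spec_sidecar(spec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"generator": type(spec).__name__, "spec": asdict(spec)}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# statistical
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatisticalGenSpec:
    """Tabular generator: informative columns are mean-shifted by
    ``effect_size`` for the positive class; the rest are pure noise."""

    n_samples: int = 270
    n_features: int = 13
    class_ratio: float = 1.25  # negative:positive
    n_informative: int = 5
    effect_size: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.class_ratio <= 0:
            raise ValueError("class_ratio must be positive")


def gen_statistical(spec: StatisticalGenSpec) -> FeatureTable:
    rng = derive_rng(spec.seed, 100)
    n_neg, n_pos = class_counts(spec.n_samples, spec.class_ratio)
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    rng.shuffle(labels)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    X[:, : spec.n_informative] += spec.effect_size * labels[:, None]
    mask = np.zeros_like(X, dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        # keep at least one observed value per column
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(0, spec.n_samples), j] = False
    names = [f"attr_{j}" for j in range(spec.n_features)]
    return FeatureTable(np.where(mask, 0.0, X), mask, labels, names)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGenSpec:
    """Image generator: class-1 images carry additive bright Gaussian blobs
    over a noisy background; sizes vary to exercise resizing."""

    n_samples: int = 200
    class_ratio: float = 0.37  # negative:positive, as in a pneumonia-skewed cohort
    size_range: tuple[int, int] = (48, 96)  # min/max of height and width
    contrast: float = 0.5
    n_blobs: int = 3
    noise_sd: float = 0.05
    background: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 8 or hi < lo:
            raise ValueError("size_range must satisfy 8 <= min <= max")
        if not 0 <= self.background <= 1 or not 0 <= self.contrast <= 1:
            raise ValueError("intensities must lie in [0,1]")


def gen_images(spec: ImageGenSpec) -> ImageStack:
    rng = derive_rng(spec.seed, 200)
    n_neg, n_pos = class_counts(spec.n_samples, spec.class_ratio)
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    rng.shuffle(labels)
    lo, hi = spec.size_range
    images = []
    for lab in labels:
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        im = spec.background + spec.noise_sd * rng.standard_normal((h, w))
        if lab == 1:
            yy, xx = np.mgrid[0:h, 0:w]
            for _ in range(spec.n_blobs):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                s = rng.uniform(0.08, 0.2) * min(h, w)
                im += spec.contrast * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        images.append(np.clip(im, 0.0, 1.0)[:, :, None])
    return ImageStack(images, labels)


# ---------------------------------------------------------------------------
# sequential
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequentialGenSpec:
    """Actigraphy-style cohort: per-participant minute series with a
    class-dependent circadian sinusoid, noise, and contiguous device-off
    missing segments."""

    n_participants: int = 55
    class_ratio: float = 32 / 23  # control:depressed participants
    days_range: tuple[int, int] = (8, 14)
    amplitude_neg: float = 5.0  # control (label 0) circadian amplitude
    amplitude_pos: float = 1.0  # depressed (label 1): flattened rhythm
    noise_sd: float = 1.0
    missing_segments_per_day: float = 0.5
    missing_segment_minutes: tuple[int, int] = (30, 240)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.days_range
        if lo < 1 or hi < lo:
            raise ValueError("days_range must satisfy 1 <= min <= max")
        if hi < 7:
            raise ValueError("at least one participant must be able to span 7 days")
        if self.missing_segments_per_day < 0:
            raise ValueError("missing_segments_per_day must be >= 0")
        lo_m, hi_m = self.missing_segment_minutes
        if lo_m < 1 or hi_m < lo_m or lo_m >= MINUTES_PER_DAY:
            raise ValueError("missing_segment_minutes must be a sane (min, max) in minutes")


def gen_sequential(spec: SequentialGenSpec) -> RecordingSet:
    rng = derive_rng(spec.seed, 300)
    n_neg, n_pos = class_counts(spec.n_participants, spec.class_ratio)
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    rng.shuffle(labels)
    minute = np.arange(MINUTES_PER_DAY)
    circadian = -np.cos(2 * np.pi * minute / MINUTES_PER_DAY)  # trough at midnight, peak midday
    recordings = []
    for i, lab in enumerate(labels):
        days = int(rng.integers(spec.days_range[0], spec.days_range[1] + 1))
        amp = spec.amplitude_pos if lab == 1 else spec.amplitude_neg
        base = amp  # keeps the noiseless signal non-negative
        series = base + amp * np.tile(circadian, days) + spec.noise_sd * rng.standard_normal(days * MINUTES_PER_DAY)
        series = np.maximum(series, 0.0)
        mask = np.zeros(days * MINUTES_PER_DAY, dtype=bool)
        n_segments = rng.poisson(spec.missing_segments_per_day * days) if spec.missing_segments_per_day else 0
        for _ in range(n_segments):
            length = int(rng.integers(spec.missing_segment_minutes[0], spec.missing_segment_minutes[1] + 1))
            start = int(rng.integers(0, len(series) - length))
            mask[start : start + length] = True
        if mask.all():
            raise ValueError("missing-segment configuration wiped out an entire series")
        recordings.append(
            Recording(
                participant_id=f"p{i:03d}",
                label=int(lab),
                values=np.where(mask, 0.0, series),
                missing_mask=mask,
            )
        )
    return RecordingSet(recordings)


# ---------------------------------------------------------------------------
# presets pinned to the benchmark shapes
# ---------------------------------------------------------------------------


def hdu_like(seed: int = 0, **overrides) -> StatisticalGenSpec:
    """270 samples × 13 attributes, class ratio 1.25 (150 normal : 120 disease)."""
    kw = {"n_samples": 270, "n_features": 13, "class_ratio": 1.25, "seed": seed}
    kw.update(overrides)
    return StatisticalGenSpec(**kw)


def xray_like(seed: int = 0, **overrides) -> ImageGenSpec:
    """Chest-X-ray-shaped image set: class ratio 0.37 normal:disease,
    heterogeneous sizes.  ``n_samples`` defaults to a desk-scale 200; the
    ratio, not the count, is the pinned property."""
    kw = {"n_samples": 200, "class_ratio": 0.37, "seed": seed}
    kw.update(overrides)
    return ImageGenSpec(**kw)


def depresjon_like(seed: int = 0, **overrides) -> SequentialGenSpec:
    """Wearable-actigraphy cohort: 55 participants (32 control : 23
    depressed), ≥7 whole days each at one-minute resolution, device-off
    missing segments."""
    kw = {"n_participants": 55, "class_ratio": 32 / 23, "seed": seed}
    kw.update(overrides)
    return SequentialGenSpec(**kw)


def write_dataset(spec, data, path_stem) -> None:
    """Persist a generated dataset with its YAML spec sidecar."""
    from pathlib import Path

    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(data, FeatureTable):
        data.to_csv(stem.with_suffix(".csv"))
    elif isinstance(data, RecordingSet):
        data.to_csv(stem.with_suffix(".csv"))
    elif isinstance(data, ImageStack):
        data.to_png_dir(stem)  # PNG directory: sizes may be heterogeneous
    else:
        raise TypeError(f"unsupported dataset type {type(data).__name__}")
    _spec_sidecar(spec, stem.with_suffix(".yaml"))
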