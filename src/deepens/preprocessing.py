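"""Phase-1 preprocessing for the three health-data types.

Covers mean imputation for feature tables, participant/time-of-day mean
imputation for minute-level activity recordings, train-set-fitted
standardisation, the fixed-test 10-fold 80:4:16 split, random-forest feature
ranking, seven-day moving-window sample generation, grayscale image
resizing, and convolutional-autoencoder feature extraction.  Every fitted
transform (scaler, autoencoder, ranking) sees the training partition only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.transform import resize as _sk_resize
from sklearn.ensemble import RandomForestClassifier

from .clu import derive_rng
from .nn import Activation, Conv2D, Dense, Flatten, MaxPool2D, Network, Reshape, UpSample2D

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

__all__ = [
    "FeatureTable",
    "ScalerParams",
    "Recording",
    "RecordingSet",
    "WindowSet",
    "ImageStack",
    "SplitSpec",
    "CAEModel",
    "impute_feature_mean",
    "impute_participant_time_mean",
    "fit_standard_scaler",
    "apply_standard_scaler",
    "invert_standard_scaler",
    "split_dataset",
    "apportion",
    "rank_features_rf",
    "generate_windows",
    "resize_images",
    "cae_fit",
    "cae_extract",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Tabular data: n×p values, a missing mask, binary labels, names."""

    values: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a non-empty n x p matrix")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if len(self.labels) != len(self.values):
            raise ValueError("labels length mismatch")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(self.values[idx], self.missing_mask[idx], self.labels[idx], list(self.feature_names))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.missing_mask.copy(), self.labels.copy(), list(self.feature_names))

    # CSV contract: header = feature names + "label", empty cell = missing
    def to_csv(self, path) -> None:
        df = pd.DataFrame(np.where(self.missing_mask, np.nan, self.values), columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature-table CSV must contain a 'label' column")
        labels = df.pop("label").to_numpy()
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(np.nan_to_num(values), mask, labels, list(df.columns))


@dataclass
class ScalerParams:
    """Per-feature mean/sd of the standard scaler, fitted on training data."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive after degenerate-column handling")


@dataclass
class Recording:
    """One participant's minute-level activity series over whole days."""

    participant_id: str
    label: int
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.values) % MINUTES_PER_DAY:
            raise ValueError(
                f"participant {self.participant_id}: series length {len(self.values)} "
                f"is not a whole number of {MINUTES_PER_DAY}-minute days"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")

    @property
    def n_days(self) -> int:
        return len(self.values) // MINUTES_PER_DAY


@dataclass
class RecordingSet:
    """A cohort of per-participant minute-level recordings."""

    recordings: list[Recording]

    def __iter__(self):
        return iter(self.recordings)

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.recordings])

    # long-format CSV: participant_id, timestamp (ISO-8601), activity, label
    def to_csv(self, path, start: str = "2020-01-01") -> None:
        frames = []
        for rec in self.recordings:
            ts = pd.date_range(start, periods=len(rec.values), freq="min")
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": rec.participant_id,
                        "timestamp": ts,
                        "activity": np.where(rec.missing_mask, np.nan, rec.values),
                        "label": rec.label,
                    }
                )
            )
        pd.concat(frames).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RecordingSet":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        recs = []
        for pid, grp in df.groupby("participant_id", sort=False):
            grp = grp.sort_values("timestamp")
            vals = grp["activity"].to_numpy(dtype=float)
            recs.append(
                Recording(
                    participant_id=str(pid),
                    label=int(grp["label"].iloc[0]),
                    values=np.nan_to_num(vals),
                    missing_mask=np.isnan(vals),
                )
            )
        return cls(recs)


@dataclass
class WindowSet:
    """Moving-window samples: (participant, start day, 10,080-value vector, label)."""

    participant_ids: list[str]
    start_days: np.ndarray
    values: np.ndarray  # (n_samples, window_days*1440)
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def to_npz(self, path) -> None:
        np.savez(
            path,
            participant_ids=np.array(self.participant_ids),
            start_days=self.start_days,
            values=self.values,
            labels=self.labels,
        )

    @classmethod
    def from_npz(cls, path) -> "WindowSet":
        with np.load(path, allow_pickle=False) as d:
            return cls(
                participant_ids=[str(s) for s in d["participant_ids"]],
                start_days=d["start_days"],
                values=d["values"],
                labels=d["labels"],
            )


@dataclass
class ImageStack:
    """Grayscale images (possibly heterogeneous sizes) with binary labels."""

    images: list[np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images/labels length mismatch")

    def __len__(self) -> int:
        return len(self.images)

    def as_array(self) -> np.ndarray:
        """Stack into (n, H, W, 1); requires homogeneous sizes (post-resize)."""
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("images have heterogeneous shapes; resize first")
        return np.stack(self.images)

    def subset(self, idx) -> "ImageStack":
        idx = np.asarray(idx)
        return ImageStack([self.images[i] for i in idx], self.labels[idx])

    def to_npz(self, path) -> None:
        arr = self.as_array()
        np.savez(path, images=arr, labels=self.labels)

    @classmethod
    def from_npz(cls, path) -> "ImageStack":
        with np.load(path) as d:
            return cls(list(d["images"]), d["labels"])

    def to_png_dir(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (im, lab) in enumerate(zip(self.images, self.labels)):
            name = f"img_{i:05d}.png"
            iio.imwrite(directory / name, (np.squeeze(im) * 255).astype(np.uint8))
            rows.append({"filename": name, "label": int(lab)})
        pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)

    @classmethod
    def from_png_dir(cls, directory) -> "ImageStack":
        from pathlib import Path

        directory = Path(directory)
        meta = pd.read_csv(directory / "labels.csv")
        images = []
        for name in meta["filename"]:
            im = np.asarray(iio.imread(directory / name), dtype=float) / 255.0
            if im.ndim == 2:
                im = im[:, :, None]
            images.append(im)
        return cls(images, meta["label"].to_numpy())


@dataclass
class SplitSpec:
    """Train/validation/test proportions, fold count, and seed."""

    train: float = 0.80
    val: float = 0.04
    test: float = 0.16
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("train/val/test proportions must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("all proportions must be positive")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


# ---------------------------------------------------------------------------
# imputation & scaling
# ---------------------------------------------------------------------------


def impute_feature_mean(table: FeatureTable) -> FeatureTable:
    """Fill missing cells with the column mean of the non-missing entries."""
    out = table.copy()
    for j in range(out.p):
        mask = out.missing_mask[:, j]
        if mask.all():
            raise ValueError(f"feature {out.feature_names[j]!r} has no observed values to average")
        if mask.any():
            out.values[mask, j] = out.values[~mask, j].mean()
    out.missing_mask[...] = False
    return out


def impute_participant_time_mean(recordings: RecordingSet) -> RecordingSet:
    """Fill each missing minute with the same participant's mean at that
    minute-of-day across days; a minute missing on every day falls back to
    the participant's overall mean."""
    out = []
    for rec in recordings:
        if rec.missing_mask.all():
            raise ValueError(f"participant {rec.participant_id}: series entirely missing")
        vals = rec.values.reshape(rec.n_days, MINUTES_PER_DAY).copy()
        miss = rec.missing_mask.reshape(rec.n_days, MINUTES_PER_DAY)
        observed = np.where(miss, np.nan, vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN minute handled below
            minute_means = np.nanmean(observed, axis=0)
        overall = rec.values[~rec.missing_mask].mean()
        minute_means = np.where(np.isnan(minute_means), overall, minute_means)
        vals[miss] = np.broadcast_to(minute_means, vals.shape)[miss]
        out.append(
            Recording(
                participant_id=rec.participant_id,
                label=rec.label,
                values=vals.reshape(-1),
                missing_mask=np.zeros_like(rec.missing_mask),
            )
        )
    return RecordingSet(out)


def fit_standard_scaler(train: FeatureTable) -> ScalerParams:
    """Mean/sd (population form) per feature, on the training partition only.

    Zero-variance columns get sigma=1 so that scaling degrades to centering.
    """
    if train.missing_mask.any():
        raise ValueError("impute before fitting the scaler")
    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0)  # ddof=0
    degenerate = sigma == 0
    if degenerate.any():
        names = [train.feature_names[j] for j in np.flatnonzero(degenerate)]
        logger.warning("constant feature(s) %s: sigma set to 1", names)
        sigma = np.where(degenerate, 1.0, sigma)
    return ScalerParams(mu=mu, sigma=sigma)


def apply_standard_scaler(params: ScalerParams, table: FeatureTable) -> FeatureTable:
    """x_scaled = (x - mu) / sigma, columnwise."""
    out = table.copy()
    out.values = (out.values - params.mu) / params.sigma
    return out


def invert_standard_scaler(params: ScalerParams, table: FeatureTable) -> FeatureTable:
    out = table.copy()
    out.values = out.values * params.sigma + params.mu
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def apportion(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items; ties go to the
    earlier bucket."""
    quotas = [n * p for p in proportions]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    remainders = [(-(q - b), i) for i, (q, b) in enumerate(zip(quotas, base))]
    for _, i in sorted(remainders)[:short]:
        base[i] += 1
    return base


def split_dataset(n_or_labels, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Index folds of (train, val, test) at the configured proportions.

    The test set is drawn once and held fixed across folds; the remainder is
    re-permuted per fold into train/validation, mirroring repeated
    experiments against one independent test set.
    """
    n = int(n_or_labels) if np.isscalar(n_or_labels) else len(n_or_labels)
    sizes = apportion(n, [spec.train, spec.val, spec.test])
    if min(sizes) < 1:
        raise ValueError(f"n={n} too small for proportions {spec.train}:{spec.val}:{spec.test}")
    n_train, n_val, n_test = sizes
    base_rng = derive_rng(spec.seed, 10)
    perm = base_rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    rest = perm[n_test:]
    folds = []
    for k in range(spec.n_folds):
        fold_rng = derive_rng(spec.seed, 10, k + 1)
        order = fold_rng.permutation(len(rest))
        shuffled = rest[order]
        folds.append((np.sort(shuffled[:n_train]), np.sort(shuffled[n_train:]), test_idx))
    return folds


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------


def rank_features_rf(
    train: FeatureTable, n_trees: int = 100, max_depth: int | None = 2, seed: int = 0
) -> pd.DataFrame:
    """Rank features by random-forest impurity importance (100 shallow trees).

    Returns a DataFrame (feature, importance) sorted by decreasing
    importance; importances sum to 1.
    """
    if train.missing_mask.any():
        raise ValueError("impute before ranking features")
    rf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth, random_state=seed)
    rf.fit(train.values, train.labels)
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return pd.DataFrame(
        {"feature": [train.feature_names[j] for j in order], "importance": imp[order], "index": order}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# moving windows
# ---------------------------------------------------------------------------


def generate_windows(recordings: RecordingSet, window_days: int = 7, step_days: int = 1) -> WindowSet:
    """Seven-day forward moving window: one 10,080-minute sample per start
    day, advanced ``step_days`` day(s) at a time; a participant with D whole
    days yields max(0, D - window_days + 1) samples (for step 1)."""
    if window_days < 1 or step_days < 1:
        raise ValueError("window_days and step_days must be >= 1")
    wlen = window_days * MINUTES_PER_DAY
    pids: list[str] = []
    starts: list[int] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for rec in recordings:
        if rec.missing_mask.any():
            raise ValueError("impute recordings before windowing")
        d = rec.n_days
        if d < window_days:
            logger.info("participant %s has %d days (< %d): no windows", rec.participant_id, d, window_days)
            continue
        for start in range(0, d - window_days + 1, step_days):
            pids.append(rec.participant_id)
            starts.append(start)
            rows.append(rec.values[start * MINUTES_PER_DAY : start * MINUTES_PER_DAY + wlen])
            labels.append(rec.label)
    values = np.array(rows) if rows else np.empty((0, wlen))
    return WindowSet(pids, np.array(starts, dtype=int), values, np.array(labels, dtype=int))


def downsample_to_daily_profile(windows: WindowSet) -> WindowSet:
    """Average the (window_days) values at each minute-of-day, reducing each
    sample to a 1440-value daily activity profile."""
    n, wlen = windows.values.shape
    days = wlen // MINUTES_PER_DAY
    prof = windows.values.reshape(n, days, MINUTES_PER_DAY).mean(axis=1)
    return WindowSet(list(windows.participant_ids), windows.start_days.copy(), prof, windows.labels.copy())


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def resize_images(stack: ImageStack, target: tuple[int, int, int] = (200, 200, 1)) -> ImageStack:
    """Resize every image to ``target`` (bilinear), normalised to [0,1]."""
    th, tw, td = target
    if td != 1:
        raise ValueError("only single-channel targets are supported")
    out = []
    for im in stack.images:
        im = np.asarray(im)
        if im.size == 0:
            raise ValueError("zero-area image")
        if np.issubdtype(im.dtype, np.integer):
            im = im.astype(float) / np.iinfo(im.dtype).max
        else:
            im = im.astype(float)
        if im.ndim == 3 and im.shape[2] == 3:
            im = rgb2gray(im)
        im = np.squeeze(im)
        if im.ndim != 2:
            raise ValueError(f"cannot reduce image of shape {im.shape} to one channel")
        if im.shape != (th, tw):
            im = _sk_resize(im, (th, tw), order=1, anti_aliasing=False, preserve_range=True)
        out.append(np.clip(im, 0.0, 1.0)[:, :, None])
    return ImageStack(out, stack.labels.copy())


# ---------------------------------------------------------------------------
# convolutional autoencoder
# ---------------------------------------------------------------------------


@dataclass
class CAEModel:
    """Convolutional autoencoder with a dense bottleneck.

    Encoder: two conv(3x3)->ReLU->pool blocks (16 then 8 filters) and a
    dense compression to ``bottleneck_dim``; decoder mirrors it back to a
    sigmoid reconstruction.  After fitting, the frozen bottleneck
    activations serve as fixed-length image features.
    """

    network: Network
    bottleneck_index: int
    input_shape: tuple[int, int, int]
    bottleneck_dim: int
    train_losses: list[float] = field(default_factory=list)
    is_fitted: bool = False

    def encode(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        for layer in self.network.layers[: self.bottleneck_index + 1]:
            x = layer.forward(x)
        return x


def _build_cae(input_shape: tuple[int, int, int], bottleneck_dim: int, seed: int) -> CAEModel:
    h, w, c = input_shape
    if h % 4 or w % 4:
        raise ValueError("image dims must be divisible by 4 (two pooling stages)")
    rng = derive_rng(seed, 0)
    enc_filters = (16, 8)
    layers: list = []
    ch = c
    for f in enc_filters:
        layers += [Conv2D(ch, f, rng), Activation("relu"), MaxPool2D(2)]
        ch = f
    flat = (h // 4) * (w // 4) * ch
    layers += [Flatten(), Dense(flat, bottleneck_dim, rng)]
    bottleneck_index = len(layers) - 1
    layers += [Dense(bottleneck_dim, flat, rng), Activation("relu"), Reshape((h // 4, w // 4, ch))]
    layers += [UpSample2D(2), Conv2D(ch, 8, rng), Activation("relu")]
    layers += [UpSample2D(2), Conv2D(8, 16, rng), Activation("relu")]
    layers += [Conv2D(16, c, rng), Activation("sigmoid")]
    net = Network(layers, loss="mse", optimizer="adam", lr=1e-3)
    return CAEModel(net, bottleneck_index, input_shape, bottleneck_dim)


def cae_fit(
    train_images: ImageStack,
    bottleneck_dim: int = 64,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
) -> CAEModel:
    """Fit the autoencoder (inputs are their own targets) on training images."""
    X = train_images.as_array().astype(float)
    model = _build_cae(X.shape[1:], bottleneck_dim, seed)
    rng = derive_rng(seed, 1)
    n = len(X)
    target = X.reshape(n, -1)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            losses.append(model.network.train_batch(X[idx], target[idx].reshape(-1)))
        model.train_losses.append(float(np.mean(losses)))
    model.is_fitted = True
    return model


def cae_extract(model: CAEModel, images: ImageStack) -> FeatureTable:
    """Frozen-weight bottleneck features, one fixed-length row per image."""
    if not model.is_fitted:
        raise RuntimeError("CAE is not fitted")
    X = images.as_array().astype(float)
    if X.shape[1:] != model.input_shape:
        raise ValueError(f"images of shape {X.shape[1:]} do not match CAE input {model.input_shape}")
    feats = model.encode(X)
    names = [f"cae_{j}" for j in range(model.bottleneck_dim)]
    return FeatureTable(feats, np.zeros_like(feats, dtype=bool), images.labels.copy(), names)
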