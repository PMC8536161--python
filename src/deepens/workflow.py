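"""Three-phase experiment runner: preprocess, build/tune, evaluate/compare.

Phase 1 applies the data-type-appropriate preprocessing chain (all fitted
transforms derived from the training partition of each fold only).  Phase 2
fits the configured model over a grid of (number of sub-models × epochs)
and selects the point with the best validation accuracy, ties broken toward
the smaller model.  Phase 3 re-fits each model ``repetitions`` times
(re-drawn train/validation folds and shifted seeds, one fixed independent
test set) and reports each metric as mean ± standard deviation, alongside
classical comparators (random forest, gradient boosting, stacking) and a
single CLU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression

from .clu import CLU, CLUSpec, build_clu, train_clu
from .ensembles import (
    DALModel,
    DeSGELModel,
    GDLBModel,
    fit_dal,
    fit_desgel,
    fit_gdlb,
    predict_dal,
    predict_desgel,
    predict_gdlb,
)
from .evaluation import MetricReport, SummaryReport, evaluate_predictions, render_comparison_table, summarize_repeats
from .preprocessing import (
    FeatureTable,
    ImageStack,
    RecordingSet,
    SplitSpec,
    apply_standard_scaler,
    cae_extract,
    cae_fit,
    downsample_to_daily_profile,
    fit_standard_scaler,
    generate_windows,
    impute_feature_mean,
    impute_participant_time_mean,
    rank_features_rf,
    resize_images,
    split_dataset,
)
from .synthetic import (
    ImageGenSpec,
    SequentialGenSpec,
    StatisticalGenSpec,
    gen_images,
    gen_sequential,
    gen_statistical,
)

PROPOSED_MODELS = ("dal", "gdlb", "desgel")
BASELINE_MODELS = ("single_clu", "rf", "gb", "stack")

__all__ = [
    "GridSpec",
    "ExperimentConfig",
    "PreparedData",
    "Phase2Result",
    "ComparisonReport",
    "run_phase1",
    "run_phase2_grid",
    "run_phase3_compare",
    "fit_model",
    "model_state_hash",
    "demo",
    "PROPOSED_MODELS",
    "BASELINE_MODELS",
]


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: sub-model counts × epoch counts.

    The full sweep spans 5..50 sub-models and 50..500 epochs in steps of 50;
    the defaults here are the grid's low corner so that desk-scale runs stay
    cheap, and both axes accept the full ranges.
    """

    n_submodels: tuple[int, ...] = (5,)
    epochs: tuple[int, ...] = (50,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_submodels", tuple(int(v) for v in self.n_submodels))
        object.__setattr__(self, "epochs", tuple(int(v) for v in self.epochs))
        for axis in (self.n_submodels, self.epochs):
            if not axis:
                raise ValueError("grid axes must be non-empty")
            if any(v <= 0 for v in axis):
                raise ValueError("grid values must be positive")
            if list(axis) != sorted(axis):
                raise ValueError("grid values must be sorted ascending")

    @classmethod
    def full_sweep(cls) -> "GridSpec":
        return cls(n_submodels=tuple(range(5, 51, 5)), epochs=tuple(range(50, 501, 50)))


@dataclass
class ExperimentConfig:
    """End-to-end description of one experiment."""

    data_type: str = "statistical"
    generator: object | None = None  # StatisticalGenSpec / ImageGenSpec / SequentialGenSpec
    data_path: str | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    model: str = "dal"
    clu: CLUSpec = field(default_factory=lambda: CLUSpec(kind="mlp", layer_sizes=(16, 8, 1)))
    grid: GridSpec = field(default_factory=GridSpec)
    repetitions: int = 10
    seed: int = 0
    image_size: tuple[int, int, int] = (200, 200, 1)
    window_days: int = 7
    daily_profile: bool = True
    sequence_bin_minutes: int = 15
    cae_bottleneck: int = 32
    cae_epochs: int = 5

    def __post_init__(self) -> None:
        if self.data_type not in {"statistical", "image", "sequential"}:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.model not in PROPOSED_MODELS + BASELINE_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        expected_kind = {"statistical": "mlp", "image": "cnn", "sequential": "rnn"}[self.data_type]
        if self.model in PROPOSED_MODELS + ("single_clu",) and self.clu.kind != expected_kind:
            raise ValueError(f"data_type {self.data_type!r} pairs with CLU kind {expected_kind!r}, got {self.clu.kind!r}")


@dataclass
class PreparedFold:
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    # CAE features for classical models on image data
    F_train: np.ndarray | None = None
    F_val: np.ndarray | None = None
    F_test: np.ndarray | None = None


@dataclass
class PreparedData:
    folds: list[PreparedFold]
    y_test: np.ndarray
    artifacts: dict = field(default_factory=dict)


def _load_or_generate(config: ExperimentConfig):
    if config.generator is not None:
        gen = config.generator
        if isinstance(gen, StatisticalGenSpec):
            return gen_statistical(gen)
        if isinstance(gen, ImageGenSpec):
            return gen_images(gen)
        if isinstance(gen, SequentialGenSpec):
            return gen_sequential(gen)
        raise TypeError(f"unsupported generator {type(gen).__name__}")
    if config.data_path is None:
        raise ValueError("config needs a generator spec or a data_path")
    if config.data_type == "statistical":
        return FeatureTable.from_csv(config.data_path)
    if config.data_type == "sequential":
        return RecordingSet.from_csv(config.data_path)
    from pathlib import Path

    path = Path(config.data_path)
    return ImageStack.from_png_dir(path) if path.is_dir() else ImageStack.from_npz(path)


def _needs_cae(models) -> bool:
    return any(m in {"rf", "gb", "stack"} for m in models)


def run_phase1(config: ExperimentConfig, for_models: tuple[str, ...] | None = None) -> PreparedData:
    """Preprocess the configured dataset into leakage-free per-fold arrays."""
    models = for_models or (config.model,)
    data = _load_or_generate(config)
    if config.data_type == "statistical":
        return _phase1_statistical(config, data)
    if config.data_type == "image":
        return _phase1_image(config, data, _needs_cae(models))
    return _phase1_sequential(config, data)


def _phase1_statistical(config: ExperimentConfig, table: FeatureTable) -> PreparedData:
    table = impute_feature_mean(table)
    folds_idx = split_dataset(table.n, config.split)
    test_idx = folds_idx[0][2]
    folds = []
    for train_idx, val_idx, _ in folds_idx:
        train = table.subset(train_idx)
        scaler = fit_standard_scaler(train)
        sc = lambda idx: apply_standard_scaler(scaler, table.subset(idx)).values  # noqa: E731
        folds.append(
            PreparedFold(
                X_train=sc(train_idx),
                y_train=table.labels[train_idx],
                X_val=sc(val_idx),
                y_val=table.labels[val_idx],
                X_test=sc(test_idx),
            )
        )
    first_train = table.subset(folds_idx[0][0])
    scaler0 = fit_standard_scaler(first_train)
    ranking = rank_features_rf(apply_standard_scaler(scaler0, first_train), seed=config.seed)
    return PreparedData(folds=folds, y_test=table.labels[test_idx], artifacts={"scaler": scaler0, "ranking": ranking})


def _phase1_image(config: ExperimentConfig, stack: ImageStack, needs_cae: bool) -> PreparedData:
    stack = resize_images(stack, target=config.image_size)
    X = stack.as_array()
    y = stack.labels
    folds_idx = split_dataset(len(stack), config.split)
    test_idx = folds_idx[0][2]
    folds = []
    caes = []
    for train_idx, val_idx, _ in folds_idx:
        fold = PreparedFold(
            X_train=X[train_idx],
            y_train=y[train_idx],
            X_val=X[val_idx],
            y_val=y[val_idx],
            X_test=X[test_idx],
        )
        if needs_cae:
            cae = cae_fit(
                stack.subset(train_idx),
                bottleneck_dim=config.cae_bottleneck,
                epochs=config.cae_epochs,
                seed=config.seed,
            )
            caes.append(cae)
            fold.F_train = cae_extract(cae, stack.subset(train_idx)).values
            fold.F_val = cae_extract(cae, stack.subset(val_idx)).values
            fold.F_test = cae_extract(cae, stack.subset(test_idx)).values
        folds.append(fold)
    return PreparedData(folds=folds, y_test=y[test_idx], artifacts={"caes": caes})


def _phase1_sequential(config: ExperimentConfig, recordings: RecordingSet) -> PreparedData:
    recordings = impute_participant_time_mean(recordings)
    windows = generate_windows(recordings, window_days=config.window_days)
    if config.daily_profile:
        windows = downsample_to_daily_profile(windows)
    X = windows.values
    if config.sequence_bin_minutes > 1:
        n, length = X.shape
        bins = length // config.sequence_bin_minutes
        X = X[:, : bins * config.sequence_bin_minutes].reshape(n, bins, config.sequence_bin_minutes).mean(axis=2)
    y = windows.labels
    folds_idx = split_dataset(len(X), config.split)
    test_idx = folds_idx[0][2]
    folds = []
    for train_idx, val_idx, _ in folds_idx:
        mu = X[train_idx].mean()
        sd = X[train_idx].std() or 1.0
        norm = lambda A: (A - mu) / sd  # noqa: E731
        folds.append(
            PreparedFold(
                X_train=norm(X[train_idx]),
                y_train=y[train_idx],
                X_val=norm(X[val_idx]),
                y_val=y[val_idx],
                X_test=norm(X[test_idx]),
            )
        )
    return PreparedData(folds=folds, y_test=y[test_idx], artifacts={"n_windows": len(X)})


# ---------------------------------------------------------------------------
# phase 2: model building & tuning
# ---------------------------------------------------------------------------


def _flat(X: np.ndarray) -> np.ndarray:
    return X.reshape(len(X), -1)


def fit_model(
    config: ExperimentConfig,
    model_name: str,
    fold: PreparedFold,
    n_submodels: int,
    epochs: int,
    seed: int,
):
    """Fit one model on one fold; returns (fitted model, score function)."""
    train = (fold.X_train, fold.y_train)
    val = (fold.X_val, fold.y_val)
    spec = config.clu.replace(epochs=epochs, seed=seed)
    if model_name == "dal":
        model = fit_dal(train, val, spec, n_members=n_submodels, seed=seed)
        return model, lambda X: predict_dal(model, X).scores
    if model_name == "gdlb":
        reg = spec.replace(output_mode="regression", loss="mean_squared_error", optimizer="sgd", initial_lr=0.01)
        model = fit_gdlb(train, val, reg, n_boosters=n_submodels, lr_policy="uniform", seed=seed)
        return model, lambda X: predict_gdlb(model, X).scores
    if model_name == "desgel":
        model = fit_desgel(train, val, spec, n_members=n_submodels, level1_spec="logistic", seed=seed)
        return model, lambda X: predict_desgel(model, X).scores
    if model_name == "single_clu":
        clu = build_clu(spec)
        clu, _ = train_clu(clu, train, val)
        return clu, clu.predict_proba
    # classical comparators operate on flat features (CAE features for images)
    Ftr = fold.F_train if fold.F_train is not None else _flat(fold.X_train)
    if model_name == "rf":
        model = RandomForestClassifier(n_estimators=n_submodels * 20, random_state=seed)
    elif model_name == "gb":
        model = GradientBoostingClassifier(n_estimators=n_submodels * 20, random_state=seed)
    elif model_name == "stack":
        model = StackingClassifier(
            estimators=[
                ("rf", RandomForestClassifier(n_estimators=n_submodels * 20, random_state=seed)),
                ("gb", GradientBoostingClassifier(n_estimators=n_submodels * 20, random_state=seed)),
            ],
            final_estimator=LogisticRegression(max_iter=1000),
            cv=3,
        )
    else:
        raise ValueError(f"unknown model {model_name!r}")
    model.fit(Ftr, fold.y_train)

    def scores(X: np.ndarray, _m=model, _fold=fold) -> np.ndarray:
        if _fold.F_test is not None and X is _fold.X_test:
            X = _fold.F_test
        elif _fold.F_val is not None and X is _fold.X_val:
            X = _fold.F_val
        elif _fold.F_train is not None and X is _fold.X_train:
            X = _fold.F_train
        else:
            X = _flat(X)
        return _m.predict_proba(X)[:, 1]

    return model, scores


@dataclass
class Phase2Result:
    model: object
    score_fn: object
    tuning_table: pd.DataFrame
    best: tuple[int, int]  # (n_submodels, epochs)


def run_phase2_grid(config: ExperimentConfig, prepared: PreparedData) -> Phase2Result:
    """Sweep the grid on fold 0, select by validation accuracy (ties toward
    fewer sub-models, then fewer epochs), and refit the winner."""
    if not config.grid.n_submodels or not config.grid.epochs:
        raise ValueError("empty hyperparameter grid")
    fold = prepared.folds[0]
    rows = []
    for s in config.grid.n_submodels:
        for e in config.grid.epochs:
            _, score_fn = fit_model(config, config.model, fold, s, e, config.seed)
            val_acc = float(np.mean((score_fn(fold.X_val) >= 0.5).astype(int) == fold.y_val))
            rows.append({"n_submodels": s, "epochs": e, "val_accuracy": val_acc})
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["val_accuracy", "n_submodels", "epochs"], ascending=[False, True, True]).iloc[0]
    best = (int(best_row["n_submodels"]), int(best_row["epochs"]))
    model, score_fn = fit_model(config, config.model, fold, best[0], best[1], config.seed)
    return Phase2Result(model=model, score_fn=score_fn, tuning_table=table, best=best)


# ---------------------------------------------------------------------------
# phase 3: repeated evaluation & comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    rows: dict[str, SummaryReport]
    group_means: dict[str, dict[str, float]]
    repetitions: int
    per_rep: dict[str, list[MetricReport]] = field(default_factory=dict)

    def render(self) -> str:
        return render_comparison_table(self.rows, self.group_means)

    def to_dict(self) -> dict:
        return {
            "repetitions": self.repetitions,
            "models": {
                name: {"mean": s.means, "std": s.stds} for name, s in self.rows.items()
            },
            "group_means": self.group_means,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        records = []
        for name, s in self.rows.items():
            rec = {"model": name}
            for k in s.means:
                rec[f"{k}_mean"] = s.means[k]
                rec[f"{k}_std"] = s.stds[k]
            records.append(rec)
        pd.DataFrame(records).to_csv(path, index=False)


def run_phase3_compare(
    config: ExperimentConfig,
    prepared: PreparedData,
    models: tuple[str, ...] = PROPOSED_MODELS + BASELINE_MODELS,
    best_params: dict[str, tuple[int, int]] | None = None,
) -> ComparisonReport:
    """Evaluate every model on the fixed test set over ``repetitions``
    re-seeded fits (train/val fold rotates; the test partition never moves)."""
    if not models:
        raise ValueError("no models to compare")
    rows: dict[str, SummaryReport] = {}
    per_rep: dict[str, list[MetricReport]] = {}
    defaults = (config.grid.n_submodels[0], config.grid.epochs[0])
    for name in models:
        n_sub, epochs = (best_params or {}).get(name, defaults)
        reports = []
        for r in range(config.repetitions):
            fold = prepared.folds[r % len(prepared.folds)]
            _, score_fn = fit_model(config, name, fold, n_sub, epochs, config.seed + r)
            reports.append(evaluate_predictions(prepared.y_test, score_fn(fold.X_test)))
        rows[name] = summarize_repeats(reports)
        per_rep[name] = reports
    group_means: dict[str, dict[str, float]] = {}
    for label, group in (("proposed (mean of means)", PROPOSED_MODELS), ("traditional (mean of means)", BASELINE_MODELS)):
        present = [m for m in group if m in rows]
        if present:
            group_means[label] = {
                k: float(np.mean([rows[m].means[k] for m in present])) for k in rows[present[0]].means
            }
    return ComparisonReport(rows=rows, group_means=group_means, repetitions=config.repetitions, per_rep=per_rep)


# ---------------------------------------------------------------------------
# state hashing (leakage checks) and the end-to-end demo
# ---------------------------------------------------------------------------


def _arrays_of(model) -> list[np.ndarray]:
    if isinstance(model, CLU):
        return model.network.get_weights()
    if isinstance(model, DALModel):
        return [w for m in model.members for w in m.network.get_weights()]
    if isinstance(model, GDLBModel):
        out = [np.array([model.p_base]), np.array(model.learning_rates)]
        for b in model.boosters:
            if isinstance(b, CLU):
                out.extend(b.network.get_weights())
        return out
    if isinstance(model, DeSGELModel):
        out = [w for m in model.level0 for w in m.network.get_weights()]
        if hasattr(model.level1, "coef_"):
            out.extend([model.level1.coef_, model.level1.intercept_])
        return out
    if hasattr(model, "feature_importances_"):
        return [model.feature_importances_]
    import pickle

    return [np.frombuffer(pickle.dumps(model), dtype=np.uint8)]


def model_state_hash(model) -> str:
    """SHA-256 over every fitted parameter array (order-stable)."""
    h = hashlib.sha256()
    for arr in _arrays_of(model):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def demo(
    data_type: str = "statistical",
    seed: int = 0,
    fast: bool = True,
    outdir=None,
    models: tuple[str, ...] = PROPOSED_MODELS + BASELINE_MODELS,
) -> ComparisonReport:
    """End-to-end run on a benchmark-shaped synthetic preset.

    ``fast`` shrinks sample counts, grid and repetitions so the whole run
    finishes in minutes on one CPU; outputs (JSON, CSV and a formatted text
    grid) are written to ``outdir`` when given.
    """
    from .synthetic import depresjon_like, hdu_like, xray_like

    reps = 3 if fast else 10
    if data_type == "statistical":
        config = ExperimentConfig(
            data_type="statistical",
            generator=hdu_like(seed=seed, effect_size=2.0),
            split=SplitSpec(seed=seed),
            clu=CLUSpec(kind="mlp", layer_sizes=(16, 8, 1), epochs=50, seed=seed),
            grid=GridSpec(n_submodels=(5,), epochs=(50,)),
            repetitions=reps,
            seed=seed,
        )
    elif data_type == "image":
        config = ExperimentConfig(
            data_type="image",
            generator=xray_like(seed=seed, n_samples=80 if fast else 200, size_range=(24, 48)),
            split=SplitSpec(seed=seed),
            model="dal",
            clu=CLUSpec(kind="cnn", layer_sizes=(16, 1), conv_filters=(4, 8), epochs=5 if fast else 20, seed=seed),
            grid=GridSpec(n_submodels=(3,), epochs=(5 if fast else 20,)),
            repetitions=min(reps, 3),
            seed=seed,
            image_size=(32, 32, 1),
            cae_epochs=3,
            cae_bottleneck=16,
        )
    elif data_type == "sequential":
        config = ExperimentConfig(
            data_type="sequential",
            generator=depresjon_like(seed=seed, n_participants=20 if fast else 55),
            split=SplitSpec(seed=seed),
            model="desgel",
            clu=CLUSpec(kind="rnn", layer_sizes=(16, 1), rnn_units=16, epochs=10 if fast else 50, seed=seed),
            grid=GridSpec(n_submodels=(3,), epochs=(10 if fast else 50,)),
            repetitions=min(reps, 3),
            seed=seed,
            sequence_bin_minutes=30,
        )
    else:
        raise ValueError(f"unknown data_type {data_type!r}")
    prepared = run_phase1(config, for_models=models)
    report = run_phase3_compare(config, prepared, models=models)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        report.to_csv(outdir / "report.csv")
        (outdir / "table.txt").write_text(report.render() + "\n")
    return report


def config_to_yaml(config: ExperimentConfig) -> str:
    import yaml

    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = {"type": type(config.generator).__name__, **dataclasses.asdict(config.generator)}
    return yaml.safe_dump(_listify(d), sort_keys=True)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def config_from_yaml(text: str) -> ExperimentConfig:
    import yaml

    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError("experiment config YAML must be a mapping")
    gen = d.pop("generator", None)
    if gen is not None:
        kinds = {
            "StatisticalGenSpec": StatisticalGenSpec,
            "ImageGenSpec": ImageGenSpec,
            "SequentialGenSpec": SequentialGenSpec,
        }
        gen_type = gen.pop("type")
        for key in ("size_range", "days_range", "missing_segment_minutes"):
            if key in gen:
                gen[key] = tuple(gen[key])
        gen = kinds[gen_type](**gen)
    if "split" in d and isinstance(d["split"], dict):
        d["split"] = SplitSpec(**d["split"])
    if "clu" in d and isinstance(d["clu"], dict):
        d["clu"] = CLUSpec(**d["clu"])
    if "grid" in d and isinstance(d["grid"], dict):
        d["grid"] = GridSpec(**d["grid"])
    if "image_size" in d:
        d["image_size"] = tuple(d["image_size"])
    return ExperimentConfig(generator=gen, **d)
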