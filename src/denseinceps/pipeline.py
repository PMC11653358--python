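"""End-to-end orchestration: data -> fused network -> features -> selection -> reports.

A run is described by one flat :class:`RunConfig` (YAML-serializable)
and proceeds through four stages, each runnable on its own:

1. ``run_training`` — build the dataset (synthetic phantoms or an image
   folder), stratified split, balance the *training* partition by
   augmentation, train the fused network, write checkpoint + audits.
2. ``run_extract`` — tap the fusion depth-concatenation layer on the
   test partition, giving the n x 512 (scaled by ``width_scale``) deep
   feature matrix.
3. ``run_select_and_classify`` — CFO feature selection, then k-fold
   evaluation of the shallow classifier variants over the four ablation
   feature sources (dense-only / inception-only / fused / fused+CFO).
4. ``tune_hyperparameters`` — a pluggable, seeded random-search stub;
   the shipped defaults (lr 1.4e-4, momentum 0.7002, batch 64) are the
   known tuned values, so tuning is optional.

Every stage re-derives the dataset and split from the config seeds, so
a run directory can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import datagen, netspec, shallow_nets
from .cfo import CFOParams, select_features
from .runtime import NetworkModel

__all__ = [
    "RunConfig",
    "run_training",
    "run_extract",
    "run_select_and_classify",
    "tune_hyperparameters",
    "FEATURE_SOURCES",
]

FEATURE_SOURCES = ("dense", "inception", "fused", "fused+cfo")
REPORT_COLUMNS = ["Accuracy", "Sensitivity", "Precision", "F1", "FNR", "Time"]


@dataclass
class RunConfig:
    # data: either a class-per-subdirectory folder, or synthetic phantoms
    data_path: str | None = None
    n_classes: int = 5
    per_class: int = 40
    noise_sd: float = 0.05
    augment_target: int | None = None   # None = balance to max class count
    split_fraction: float = 0.7
    # network / training
    width_scale: float = 1.0
    lr: float = 1.4e-4
    momentum: float = 0.7002
    batch_size: int = 64
    epochs: int = 10
    # feature selection
    cfo_pop: int = 20
    cfo_budget: int = 2000
    cfo_lambda: float = 0.05
    cfo_repeats: int = 3    # holdout repeats inside the selection fitness
    # classification
    variants: tuple = ("NNN", "MNN", "SWNN", "BNN", "TNN")
    k_folds: int = 10
    classifier_epochs: int = 200
    seed: int = 0
    out_dir: str = "runs/run0"

    def __post_init__(self):
        for name in ("split_fraction", "width_scale", "lr", "momentum",
                     "batch_size", "epochs", "k_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        return cls(**d)

    @classmethod
    def desk_scale(cls, seed: int = 0, out_dir: str = "runs/desk") -> "RunConfig":
        """CPU-scale study conditions: the full pipeline in minutes.

        Channel widths scaled by 1/8 (structure unchanged), 200 phantoms
        (5 classes x 40), 70/30 split, training partition balanced and
        diversified by flip/rotation augmentation to 3x the per-class
        originals, 10 epochs of SGD at lr 3e-3 / momentum 0.9 / batch 16.
        The full-scale defaults (lr 1.4e-4, momentum 0.7002, batch 64)
        are tuned for 100-epoch GPU training and undertrain a run this
        short, so the desk preset uses a hotter, plainer setting.
        """
        return cls(width_scale=0.125, per_class=40, n_classes=5,
                   augment_target=84, epochs=10, lr=3e-3, momentum=0.9,
                   batch_size=16, seed=seed, out_dir=out_dir)


def _load_dataset(cfg: RunConfig) -> datagen.ImageDataset:
    if cfg.data_path:
        return datagen.load_image_folder(cfg.data_path)
    return datagen.generate_phantoms(datagen.PhantomConfig(
        n_classes=cfg.n_classes, per_class=cfg.per_class,
        noise_sd=cfg.noise_sd, seed=cfg.seed))


def _split_dataset(cfg: RunConfig, ds):
    return datagen.split(ds, cfg.split_fraction, seed=cfg.seed)


def run_training(cfg: RunConfig):
    """Split, augment (train partition only), build, train; write artifacts.

    Returns (model, audit, loss_history).
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.save(os.path.join(cfg.out_dir, "config.yaml"))
    ds = _load_dataset(cfg)
    train_ds, _ = _split_dataset(cfg, ds)
    target = cfg.augment_target or max(train_ds.class_counts.values())
    train_ds = datagen.augment(train_ds, target, seed=cfg.seed)

    graph = netspec.build_fused_network(cfg.width_scale,
                                        num_classes=len(ds.class_names))
    aud = netspec.audit(graph)
    with open(os.path.join(cfg.out_dir, "arch.json"), "w") as fh:
        fh.write(graph.to_json())
    with open(os.path.join(cfg.out_dir, "audit.json"), "w") as fh:
        fh.write(aud.to_json())

    X, y, _ = train_ds.as_arrays()
    model = NetworkModel(graph, seed=cfg.seed)
    history = model.train_epochs(X, y, epochs=cfg.epochs, lr=cfg.lr,
                                 momentum=cfg.momentum,
                                 batch_size=cfg.batch_size, seed=cfg.seed)
    model.save(os.path.join(cfg.out_dir, "checkpoint.npz"))
    pd.DataFrame({"epoch": range(len(history)), "loss": history}).to_csv(
        os.path.join(cfg.out_dir, "loss.csv"), index=False)
    return model, aud, history


def run_extract(cfg: RunConfig, checkpoint: str | None = None) -> pd.DataFrame:
    """Deep features of the test partition from the fusion concat layer."""
    checkpoint = checkpoint or os.path.join(cfg.out_dir, "checkpoint.npz")
    if not os.path.exists(checkpoint):
        raise FileNotFoundError(f"checkpoint not found: {checkpoint}")
    ds = _load_dataset(cfg)
    _, test_ds = _split_dataset(cfg, ds)
    graph = netspec.build_fused_network(cfg.width_scale,
                                        num_classes=len(ds.class_names))
    model = NetworkModel(graph, seed=cfg.seed).load(checkpoint)
    X, y, names = test_ds.as_arrays()
    feats = []
    for start in range(0, len(X), cfg.batch_size):
        feats.append(model.forward(X[start:start + cfg.batch_size],
                                   tap="fusion_concat"))
    F = np.concatenate(feats, axis=0)
    df = pd.DataFrame(F, columns=[f"f{i}" for i in range(F.shape[1])])
    df["label"] = [names[c] for c in y]
    df.to_csv(os.path.join(cfg.out_dir, "features.csv"), index=False)
    return df


def _dense_feature_dim(cfg: RunConfig) -> int:
    g = netspec.build_dense_module(cfg.width_scale)
    return netspec.infer_shapes(g)["d_attention"][0]


def run_select_and_classify(cfg: RunConfig,
                            features: pd.DataFrame | str | None = None):
    """CFO selection + k-fold evaluation over the four ablation feature sources.

    Returns (report DataFrame, SelectionMask).  The report has one row
    per (feature source, classifier variant) in Table-style column
    order; the mask and per-variant confusion matrices are written to
    the run directory.
    """
    if features is None:
        features = os.path.join(cfg.out_dir, "features.csv")
    if isinstance(features, str):
        features = pd.read_csv(features)
    labels = sorted(features["label"].unique())
    lut = {c: i for i, c in enumerate(labels)}
    y = features["label"].map(lut).to_numpy()
    X = features.drop(columns="label").to_numpy(dtype=float)

    mask = select_features(
        X, y, lam=cfg.cfo_lambda, repeats=cfg.cfo_repeats,
        params=CFOParams(M=cfg.cfo_pop, MaxEFs=cfo_budget_for(cfg),
                         seed=cfg.seed))
    os.makedirs(cfg.out_dir, exist_ok=True)
    with open(os.path.join(cfg.out_dir, "mask.json"), "w") as fh:
        json.dump({"selected_indices": mask.indices.tolist(),
                   "fitness": mask.fitness,
                   "selected_count": mask.selected_count}, fh, indent=1)

    d1 = _dense_feature_dim(cfg)
    sources = {
        "dense": X[:, :d1],
        "inception": X[:, d1:],
        "fused": X,
        "fused+cfo": X[:, mask.mask],
    }
    rows, confusions = [], {}
    for source in FEATURE_SOURCES:
        Xs = sources[source]
        for variant in cfg.variants:
            spec = shallow_nets.ClassifierSpec(
                variant=variant, input_dim=Xs.shape[1],
                n_classes=len(labels), seed=cfg.seed)
            report, _ = shallow_nets.kfold_evaluate(
                Xs, y, spec, k=cfg.k_folds, seed=cfg.seed,
                epochs=cfg.classifier_epochs)
            rows.append({
                "FeatureSource": source, "Classifier": variant,
                "Accuracy": round(report.accuracy, 2),
                "Sensitivity": round(report.sensitivity, 2),
                "Precision": round(report.precision, 2),
                "F1": round(report.f1, 2),
                "FNR": round(report.fnr, 2),
                "Time": round(report.elapsed_s, 3),
            })
            confusions[f"{source}/{variant}"] = report.confusion.tolist()
    df = pd.DataFrame(rows, columns=["FeatureSource", "Classifier"] + REPORT_COLUMNS)
    df.to_csv(os.path.join(cfg.out_dir, "report.csv"), index=False)
    with open(os.path.join(cfg.out_dir, "confusion.json"), "w") as fh:
        json.dump({"labels": labels, "confusion": confusions}, fh, indent=1)
    return df, mask


def cfo_budget_for(cfg: RunConfig) -> int:
    return max(cfg.cfo_budget, cfg.cfo_pop)


def tune_hyperparameters(space: dict, budget: int, seed: int = 0,
                         scorer=None):
    """Seeded random search over {lr, momentum, batch_size}-style spaces.

    ``space`` maps a name to either a (low, high) range, a list of
    choices, or a single point value.  ``scorer(settings) -> float``
    (lower is better) ranks the sampled settings; without a scorer the
    first sample wins.  Returns the best settings dict.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best, best_score = None, np.inf
    for _ in range(budget):
        settings = {}
        for name, spec in space.items():
            if isinstance(spec, (list, tuple)) and len(spec) == 2 \
                    and all(isinstance(v, (int, float)) for v in spec) \
                    and not isinstance(spec, list):
                lo, hi = spec
                settings[name] = float(rng.uniform(lo, hi))
            elif isinstance(spec, list):
                settings[name] = spec[int(rng.integers(len(spec)))]
            else:
                settings[name] = spec
        score = float(scorer(settings)) if scorer is not None else 0.0
        if score < best_score:
            best, best_score = settings, score
    return best
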