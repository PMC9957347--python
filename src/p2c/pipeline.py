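"""End-to-end orchestration and evaluation metrics.

``run_pipeline`` chains the stages: impulse-noise filtering and CLAHE,
backbone training and feature extraction, AOA-driven LS-SVM tuning on the
training portion of a seeded stratified 80/20 split, and final evaluation on
the held-out portion.  ``compute_metrics`` reports the confusion-matrix panel
per class (each class taken as positive in turn) and averaged: balanced
accuracy, sensitivity, specificity, F-score and MCC, all scaled to percent
(MCC is multiplied by 100 to share the scale; it lives in [-100, 100]).

A metric whose denominator vanishes is reported as NaN with a warning —
never silently as zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .backbone import DenseNetConfig, RMSPropState, SMALL_PROFILE, build_backbone, extract_features, train_backbone
from .lssvm import predict
from .preprocess import AMFConfig, CLAHEConfig, adaptive_median_filter, clahe
from .tuning import SearchSpace, TuneResult, tune

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "RunConfig", "compute_metrics", "run_pipeline"]


@dataclass
class MetricsReport:
    """Per-class and averaged classification metrics, in percent."""

    classes: list
    per_class: dict          # label -> {sensitivity, specificity, ..., tp, fp, tn, fn}
    average: dict            # metric -> mean over the two positive-class views
    n: int

    def to_dict(self) -> dict:
        return {"classes": [str(c) for c in self.classes],
                "per_class": {str(k): v for k, v in self.per_class.items()},
                "average": self.average, "n": self.n}


def _safe_ratio(num: float, den: float, name: str, positive) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for positive class {positive!r} "
                      "(zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion-matrix panel for a two-class problem.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy =
    (sens+spec)/2, F-score = 2TP/(2TP+FP+FN) and MCC, each computed once per
    class taken as positive and then averaged.  Values are percentages.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    if not np.all(np.isin(y_pred, classes)):
        raise ValueError("predictions contain labels outside the true class set")

    n = y_true.size
    per_class = {}
    for pos in classes:
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        tn = int(np.sum((y_true != pos) & (y_pred != pos)))
        sens = _safe_ratio(tp, tp + fn, "sensitivity", pos)
        spec = _safe_ratio(tn, tn + fp, "specificity", pos)
        f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F-score", pos)
        mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "MCC", pos)
        per_class[pos] = {
            "sensitivity": 100.0 * sens,
            "specificity": 100.0 * spec,
            "balanced_accuracy": 100.0 * (sens + spec) / 2.0,
            "f_score": 100.0 * f1,
            "mcc": 100.0 * mcc,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        }
    metric_names = ("balanced_accuracy", "sensitivity", "specificity", "f_score", "mcc")
    average = {m: float(np.mean([per_class[c][m] for c in classes])) for m in metric_names}
    return MetricsReport(classes=list(classes), per_class=per_class,
                         average=average, n=n)


@dataclass
class RunConfig:
    """Everything one evaluation run needs; seeds are explicit.

    Either pass in-memory ``images``/``labels`` or an ``image_dir`` plus a
    ``manifest`` CSV (``filename,label``).  The master ``seed`` derives the
    split, backbone, CV-fold and optimizer seeds (seed, seed+1, seed+2,
    seed+3), so a config reproduces its report exactly.
    """

    images: np.ndarray | None = None
    labels: np.ndarray | None = None
    image_dir: str | None = None
    manifest: str | None = None
    amf: AMFConfig = field(default_factory=AMFConfig)
    clahe_cfg: CLAHEConfig = field(default_factory=CLAHEConfig)
    backbone: DenseNetConfig = field(default_factory=lambda: SMALL_PROFILE)
    epochs: int = 5
    batch_size: int = 5
    dropout: float = 0.5
    learning_rate: float = 0.01
    space: SearchSpace = field(default_factory=SearchSpace)
    aoa_objects: int = 10
    aoa_iters: int = 15
    k_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    out_dir: str | None = None

    def config_digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("images", "labels")}
        return hashlib.sha256(repr(sorted(payload.items(), key=lambda kv: kv[0]))
                              .encode()).hexdigest()[:16]


def _stage(name: str, cfg: RunConfig):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed (config digest "
                    f"{cfg.config_digest()}, seed {cfg.seed}): {exc}"
                ) from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - self.t0)
    return _Ctx()


def run_pipeline(cfg: RunConfig) -> tuple[MetricsReport, dict]:
    """Preprocess -> train/extract features -> tune -> evaluate held-out split.

    Returns the metrics report and an artifacts dict (tune result, split
    indices, file paths when ``out_dir`` is set).
    """
    log_handler = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out / "run.log")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("p2c").addHandler(log_handler)
        logging.getLogger("p2c").setLevel(logging.INFO)
    try:
        return _run(cfg)
    finally:
        if log_handler is not None:
            logging.getLogger("p2c").removeHandler(log_handler)
            log_handler.close()


def _run(cfg: RunConfig) -> tuple[MetricsReport, dict]:
    logger.info("run start: digest=%s seed=%d", cfg.config_digest(), cfg.seed)

    with _stage("load", cfg):
        if cfg.images is not None:
            images, labels = np.asarray(cfg.images), np.asarray(cfg.labels)
        elif cfg.image_dir is not None and cfg.manifest is not None:
            from .io import read_image_dir
            images, labels = read_image_dir(cfg.image_dir, cfg.manifest)
        else:
            raise ValueError("provide images/labels arrays or image_dir + manifest")
        if np.unique(labels).size != 2:
            raise ValueError("pipeline requires exactly two classes")

    with _stage("preprocess", cfg):
        processed = np.stack([
            clahe(adaptive_median_filter(img, cfg.amf), cfg.clahe_cfg)
            for img in images
        ])

    with _stage("split", cfg):
        idx = np.arange(len(labels))
        train_idx, test_idx = train_test_split(
            idx, test_size=cfg.test_fraction, stratify=labels,
            random_state=cfg.seed)

    with _stage("backbone", cfg):
        model = build_backbone(cfg.backbone, seed=cfg.seed + 1)
        state = RMSPropState(alpha=cfg.learning_rate)
        model, loss_history = train_backbone(
            model, processed[train_idx], labels[train_idx], rmsprop=state,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            dropout=cfg.dropout, seed=cfg.seed + 1)
        feats_train = extract_features(model, processed[train_idx])
        feats_test = extract_features(model, processed[test_idx])

    with _stage("tune", cfg):
        result: TuneResult = tune(
            feats_train, labels[train_idx], cfg.space,
            n_objects=cfg.aoa_objects, tmax=cfg.aoa_iters,
            k_folds=cfg.k_folds, seed=cfg.seed + 2, aoa_seed=cfg.seed + 3)

    with _stage("evaluate", cfg):
        y_pred = predict(result.final_model, feats_test)
        report = compute_metrics(labels[test_idx], y_pred)

    artifacts: dict = {
        "tune": result,
        "loss_history": loss_history,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "config_digest": cfg.config_digest(),
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        payload = report.to_dict()
        payload["config_digest"] = cfg.config_digest()
        payload["seeds"] = {"split": cfg.seed, "backbone": cfg.seed + 1,
                            "cv_folds": cfg.seed + 2, "aoa": cfg.seed + 3}
        with open(out / "metrics.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        with open(out / "confusion.csv", "w") as fh:
            fh.write("positive_class,tp,fp,tn,fn\n")
            for c in report.classes:
                pc = report.per_class[c]
                fh.write(f"{c},{pc['tp']},{pc['fp']},{pc['tn']},{pc['fn']}\n")
        result.to_json(out / "tune.json")
        artifacts["paths"] = {name: str(out / name) for name in
                              ("metrics.json", "confusion.csv", "tune.json", "run.log")}
    logger.info("run done: averaged balanced accuracy %.2f%%",
                report.average["balanced_accuracy"])
    return report, artifacts
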