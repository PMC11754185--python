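"""End-to-end orchestration: split, scale, select, fit, persist, evaluate.

All train-only statistics (scaling, feature ranking, graph widths, ridge
priors) are estimated on the 60% training split; the 20% validation split
is used only for hyperparameter selection when a grid is requested; the
20% test split is touched once, at evaluation.
"""

from __future__ import annotations

import dataclasses
import datetime
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from lrcl.data import (
    MultiViewDataset,
    SplitPlan,
    Standardizer,
    load_views,
    standardize,
    stratified_split,
)
from lrcl.feature_selection import select_features
from lrcl.metrics import EvalReport, auc, confusion_metrics
from lrcl.solver import FitConfig, LRCLClassifier


def _log(outdir: Path, stage: str, message: str) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"{stamp}\t{stage}\t{message}\n")


def fit_pipeline(
    dataset: MultiViewDataset,
    outdir: str | Path,
    config: FitConfig,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    n_keep=None,
    score_method: str = "average_rank",
    do_standardize: bool = True,
    grid: tuple[Sequence[float], Sequence[float]] | None = None,
) -> tuple[LRCLClassifier, SplitPlan, EvalReport]:
    """Full training run on an in-memory dataset; persists a model directory.

    Returns the fitted classifier, the split plan, and the validation-split
    report of the selected model.  When ``grid`` = (alphas, betas) is given,
    each combination is fitted on train and the one with the best validation
    AUC (accuracy for multi-class) is kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log(outdir, "split", f"N={dataset.n_samples} ratios={ratios} seed={config.seed}")
    plan = stratified_split(dataset, ratios=ratios, seed=config.seed)

    scaler = None
    ds = dataset
    if do_standardize:
        ds, scaler = standardize(dataset, plan)
        n_const = sum(len(c) for c in scaler.constant_features)
        _log(outdir, "standardize", f"train-statistics z-scoring; {n_const} constant feature(s)")

    ranking = None
    if n_keep is not None:
        ds, ranking = select_features(ds, plan.train_idx, n_keep=n_keep, method=score_method)
        _log(outdir, "select", f"method={score_method} kept={ranking.n_keep}")

    tr = ds.subset(plan.train_idx)
    va = ds.subset(plan.val_idx)

    candidates = [(config.alpha, config.beta)]
    if grid is not None:
        candidates = list(itertools.product(*grid))

    best = None
    for a, b in candidates:
        cfg = dataclasses.replace(config, alpha=float(a), beta=float(b))
        clf = LRCLClassifier(**{f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)})
        clf.fit(tr.views, np.asarray(tr.labels))
        if len(clf.classes_) == 2:
            val_score = auc(
                clf.decision_function(va.views), np.asarray(va.labels),
                pos_label=clf.classes_[1],
            )
        else:
            val_score = 100.0 * float(
                np.mean(
                    np.asarray(clf.predict(va.views)).astype(str)
                    == np.asarray(va.labels).astype(str)
                )
            )
        _log(
            outdir, "fit",
            f"alpha={a} beta={b} iterations={clf.state_.iteration} "
            f"converged={clf.state_.converged} "
            f"J={clf.state_.objective_trace[-1]:.6g} "
            f"omega={np.array2string(clf.state_.omega, precision=4)} val_score={val_score:.3f}",
        )
        if best is None or val_score > best[0]:
            best = (val_score, clf, (float(a), float(b)))

    val_score, clf, (a, b) = best
    clf.save(outdir)
    preprocess = {
        "standardize": bool(do_standardize),
        "means": [m.tolist() for m in scaler.means] if scaler else None,
        "scales": [s.tolist() for s in scaler.scales] if scaler else None,
        "selected_indices": [ix.tolist() for ix in ranking.selected] if ranking else None,
        "score_method": score_method if ranking else None,
        "ratios": list(ratios),
        "split_seed": config.seed,
        "train_ids": [dataset.sample_ids[i] for i in plan.train_idx],
        "val_ids": [dataset.sample_ids[i] for i in plan.val_idx],
        "test_ids": [dataset.sample_ids[i] for i in plan.test_idx],
        "selected_alpha": a,
        "selected_beta": b,
    }
    (outdir / "preprocess.json").write_text(json.dumps(preprocess, indent=2))
    _log(outdir, "persist", f"model written to {outdir} (alpha={a}, beta={b})")

    if len(clf.classes_) == 2:
        pred = np.asarray(clf.predict(va.views)).astype(str)
        report = confusion_metrics(pred, np.asarray(va.labels).astype(str), pos_label=str(clf.classes_[1]))
        report.AUC = val_score
    else:
        report = EvalReport(SP=None, SN=None, ACC=val_score)
    return clf, plan, report


def _apply_preprocess(views: list[np.ndarray], preprocess: dict) -> list[np.ndarray]:
    if preprocess["standardize"]:
        scaler = Standardizer(
            means=[np.asarray(m) for m in preprocess["means"]],
            scales=[np.asarray(s) for s in preprocess["scales"]],
            constant_features=[np.asarray([], dtype=int) for _ in preprocess["means"]],
        )
        views = scaler.transform(views)
    if preprocess["selected_indices"] is not None:
        views = [X[:, np.asarray(ix, dtype=int)] for X, ix in zip(views, preprocess["selected_indices"])]
    return views


def load_model_dir(model_dir: str | Path) -> tuple[LRCLClassifier, dict]:
    model_dir = Path(model_dir)
    clf = LRCLClassifier.load(model_dir)
    preprocess = json.loads((model_dir / "preprocess.json").read_text())
    return clf, preprocess


def predict_tables(
    model_dir: str | Path, view_paths: Sequence[str | Path]
) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Predict classes (and binary scores) for new per-view tables."""
    clf, preprocess = load_model_dir(model_dir)
    ds = load_views(view_paths, label_path=None)
    views = _apply_preprocess(ds.views, preprocess)
    pred = clf.predict(views)
    score = clf.decision_function(views) if len(clf.classes_) == 2 else None
    return ds.sample_ids, pred, score


def evaluate_split(
    model_dir: str | Path,
    dataset: MultiViewDataset,
    split: str = "test",
) -> EvalReport:
    """Evaluate a persisted model on one split of the original dataset."""
    clf, preprocess = load_model_dir(model_dir)
    ids = preprocess[f"{split}_ids"]
    pos_by_id = {s: i for i, s in enumerate(dataset.sample_ids)}
    missing = [s for s in ids if s not in pos_by_id]
    if missing:
        raise ValueError(f"dataset is missing persisted {split} samples: {missing[:5]}")
    idx = np.asarray([pos_by_id[s] for s in ids], dtype=int)
    sub = dataset.subset(idx)
    views = _apply_preprocess(sub.views, preprocess)
    truth = np.asarray(sub.labels).astype(str)
    pred = np.asarray(clf.predict(views)).astype(str)
    if len(clf.classes_) == 2:
        report = confusion_metrics(pred, truth, pos_label=str(clf.classes_[1]))
        report.AUC = auc(clf.decision_function(views), truth, pos_label=str(clf.classes_[1]))
    else:
        report = EvalReport(SP=None, SN=None, ACC=100.0 * float(np.mean(pred == truth)))
    return report
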