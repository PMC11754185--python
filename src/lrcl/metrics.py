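"""Classification metrics (SP/SN/ACC/AUC, percent scale) and the ablation harness.

The ablation harness runs the full model against its two stripped variants
(consistency term removed, manifold term removed) over many synthetic
seeds, recording per-iteration train/test AUC so that the effect of each
regularizer on accuracy and on the train-test generalization gap can be
asserted statistically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from lrcl.data import standardize, stratified_split
from lrcl.feature_selection import select_features
from lrcl.solver import FitConfig, LRCLClassifier, predict_scores


@dataclass
class EvalReport:
    """Binary classification metrics on the percent scale.

    Metrics with an empty denominator (e.g. specificity when no negatives
    were evaluated) are reported as None, never silently as 0.
    """

    SP: float | None
    SN: float | None
    ACC: float
    AUC: float | None = None
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_metrics(predicted, truth, pos_label) -> EvalReport:
    """Specificity, sensitivity and accuracy from a binary confusion table."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size < 1:
        raise ValueError("predicted and truth must be equal-length, nonempty")
    labels = set(np.unique(truth)) | set(np.unique(predicted))
    if pos_label not in labels:
        raise ValueError(f"positive class {pos_label!r} not among labels {labels}")
    if len(labels) > 2:
        raise ValueError(f"binary metrics got more than two labels: {labels}")
    neg = (labels - {pos_label}).pop() if len(labels) == 2 else None

    y_true = (truth == pos_label).astype(int)
    y_pred = (predicted == pos_label).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    n = len(truth)
    sn = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    sp = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    acc = 100.0 * (tp + tn) / n
    return EvalReport(SP=sp, SN=sn, ACC=acc, TP=int(tp), FP=int(fp), TN=int(tn), FN=int(fn))


def auc(scores, truth, pos_label=None) -> float:
    """Rank-based (Mann-Whitney) AUC on the 0-100 scale, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if len(classes) != 2:
        raise ValueError(
            f"AUC needs both classes present, got {classes.tolist()}"
        )
    pos = classes[1] if pos_label is None else pos_label
    y = (truth == pos).astype(int)
    return 100.0 * float(roc_auc_score(y, scores))


@dataclass
class AblationResult:
    """Per-seed outcomes and iteration traces for one ablation mode."""

    mode: str
    final_test_auc: list[float] = field(default_factory=list)
    final_train_auc: list[float] = field(default_factory=list)
    traces: pd.DataFrame | None = None

    @property
    def gaps(self) -> np.ndarray:
        return np.asarray(self.final_train_auc) - np.asarray(self.final_test_auc)

    def summary(self) -> dict:
        test = np.asarray(self.final_test_auc)
        gap = self.gaps
        n = len(test)
        return {
            "mode": self.mode,
            "n_seeds": n,
            "mean_test_auc": float(test.mean()),
            "sd_test_auc": float(test.std(ddof=1)) if n > 1 else None,
            "mean_gap": float(gap.mean()),
            "sd_gap": float(gap.std(ddof=1)) if n > 1 else None,
        }


_MODES = ("full", "no_consistency", "no_manifold")


def _mode_config(config: FitConfig, mode: str) -> FitConfig:
    if mode == "full":
        return config
    if mode == "no_consistency":
        return dataclasses.replace(config, beta=0.0)
    if mode == "no_manifold":
        return dataclasses.replace(config, alpha=0.0)
    raise ValueError(f"unknown ablation mode {mode!r}; choose from {_MODES}")


def ablation_run(
    mode: str,
    seeds,
    config: FitConfig | None = None,
    spec=None,
    n_keep=None,
    ratios=(0.6, 0.2, 0.2),
) -> AblationResult:
    """Fit one model variant over many fresh synthetic datasets.

    For each seed a new dataset is generated, split 60/20/20, standardized
    and (optionally) feature-selected on the training split, then fitted;
    train and test AUC are recorded at every solver iteration.  The same
    seed drives data generation, splitting and solver initialization, so a
    repeated call is bitwise identical.
    """
    from lrcl.simulate import GeneratorSpec, generate  # late: avoid import cycle

    base_config = config if config is not None else FitConfig()
    cfg_template = _mode_config(base_config, mode)
    base_spec = spec if spec is not None else GeneratorSpec()

    result = AblationResult(mode=mode)
    trace_rows = []
    for seed in seeds:
        ds = generate(dataclasses.replace(base_spec, seed=int(seed)))
        plan = stratified_split(ds, ratios=ratios, seed=int(seed))
        ds_std, _ = standardize(ds, plan)
        if n_keep is not None:
            ds_std, _ = select_features(
                ds_std, plan.train_idx, n_keep=n_keep, method="average_rank"
            )
        tr = ds_std.subset(plan.train_idx)
        te = ds_std.subset(plan.test_idx)

        cfg = dataclasses.replace(cfg_template, seed=int(seed))
        clf = LRCLClassifier(**{f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)})

        classes = sorted(set(np.asarray(tr.labels).tolist()))
        pos = classes[1]

        def record(it, state, tr=tr, te=te, pos=pos, seed=seed):
            for split_name, split_ds in (("train", tr), ("test", te)):
                S = predict_scores(split_ds.views, state.Z, state.omega)
                j_pos = classes.index(pos)
                score = S[:, j_pos] - S[:, 1 - j_pos]
                trace_rows.append(
                    {
                        "seed": seed,
                        "iteration": it,
                        "split": split_name,
                        "auc": auc(score, np.asarray(split_ds.labels), pos_label=pos),
                    }
                )

        clf.fit(tr.views, np.asarray(tr.labels), monitor=record)
        result.final_train_auc.append(
            auc(clf.decision_function(tr.views, pos_label=pos), np.asarray(tr.labels), pos_label=pos)
        )
        result.final_test_auc.append(
            auc(clf.decision_function(te.views, pos_label=pos), np.asarray(te.labels), pos_label=pos)
        )

    result.traces = pd.DataFrame(trace_rows)
    return result
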