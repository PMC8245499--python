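"""Confusion bookkeeping, the five performance metrics, and repeated CV.

The protocol: stratified five-fold cross-validation, repeated five times
with fresh random fold assignments; within one repetition the five held-out
folds' predictions are pooled into a single confusion table (so each
repetition yields one measurement per metric), and the mean and standard
deviation over repetitions are reported.  For the two-step model the
subtype rule is applied before fold assignment, so every subtype model is
validated on held-out members of its own subtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grouping import assign_group
from .model import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, ACPClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, pos_label="ACP") -> ConfusionCounts:
    """Binary confusion counts with ``pos_label`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    t = y_true == pos_label
    p = y_pred == pos_label
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity, accuracy, balanced accuracy and MCC.

    Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP),
    Accuracy = (TP+TN)/total, Balanced accuracy = (Sen+Spec)/2,
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero denominator yields 0 by convention.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
        }


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five metrics from a confusion table."""
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    acc = (c.tp + c.tn) / c.total if c.total else 0.0
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(
        sensitivity=sen,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=(sen + spec) / 2.0,
        mcc=mcc,
    )


METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "balanced_accuracy", "mcc")


@dataclass
class CvResult:
    reports: list[MetricsReport]
    folds: int
    repetitions: int
    seed: int
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        table = np.array([[getattr(r, m) for m in METRIC_NAMES] for r in self.reports])
        self.mean = dict(zip(METRIC_NAMES, table.mean(axis=0)))
        if len(self.reports) > 1:
            self.sd = dict(zip(METRIC_NAMES, table.std(axis=0, ddof=1)))
        else:
            self.sd = {m: 0.0 for m in METRIC_NAMES}

    def summary_row(self, label: str = "") -> pd.DataFrame:
        """One-row frame in benchmark-table layout: percentages as
        ``mean ± SD`` for Sen/Spec/Acc/BAcc, MCC on its own scale."""
        cells = {"feature_set": label}
        for m, col in zip(METRIC_NAMES, ("Sen", "Spec", "Acc", "BAcc", "MCC")):
            scale = 1.0 if m == "mcc" else 100.0
            prec = 2 if m == "mcc" else 2
            cells[col] = f"{self.mean[m] * scale:.{prec}f} ± {self.sd[m] * scale:.{prec}f}"
        return pd.DataFrame([cells])


def _fold_assignment(strata: pd.Series, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold ids, balanced within every stratum."""
    fold_id = np.empty(len(strata), dtype=int)
    for _, idx in strata.groupby(strata).groups.items():
        pos = strata.index.get_indexer(idx)
        if len(pos) < folds:
            raise ValueError(
                f"stratum with {len(pos)} members cannot fill {folds} folds"
            )
        perm = rng.permutation(len(pos))
        fold_id[pos[perm]] = np.arange(len(pos)) % folds
    return fold_id


def repeated_cv(
    ds: pd.DataFrame,
    features="aac+dpc+pcp",
    mode: str = "two_step",
    folds: int = 5,
    reps: int = 5,
    seed: int = 0,
    pool: bool = True,
    window: int = 5,
    pH: float = 7.0,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    inner_cv: int = 5,
    scoring: str = "accuracy",
    class_weight=None,
    pos_label: str = "ACP",
) -> CvResult:
    """Repeated stratified k-fold cross-validation of the classifier.

    Parameters beyond the protocol knobs (``folds``, ``reps``, ``seed``)
    configure the underlying :class:`ACPClassifier`.  ``mode`` is
    ``"two_step"`` or ``"one_step"``.  With ``pool=True`` (default) the
    held-out folds of one repetition are combined into a single confusion
    table; ``pool=False`` averages per-fold metric values instead.
    """
    if mode not in ("one_step", "two_step"):
        raise ValueError(f"mode must be one_step or two_step, got {mode!r}")
    two_step = mode == "two_step"
    ds = ds.reset_index(drop=True)
    labels = ds["label"]
    if two_step:
        groups = ds["sequence"].map(lambda s: assign_group(s, window).group.value)
        strata = groups + "/" + labels
    else:
        strata = labels.copy()

    reports = []
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        fold_id = _fold_assignment(strata, folds, rng)
        fold_reports = []
        y_true_all, y_pred_all = [], []
        for f in range(folds):
            test_mask = fold_id == f
            clf = ACPClassifier(
                features=features,
                two_step=two_step,
                window=window,
                pH=pH,
                C_grid=C_grid,
                gamma_grid=gamma_grid,
                cv=inner_cv,
                scoring=scoring,
                class_weight=class_weight,
                pos_label=pos_label,
                random_state=seed + 100 * rep + f,
            )
            clf.fit(ds.loc[~test_mask, "sequence"].tolist(), labels[~test_mask].to_numpy())
            y_pred = clf.predict(ds.loc[test_mask, "sequence"].tolist())
            y_true = labels[test_mask].to_numpy()
            if pool:
                y_true_all.append(y_true)
                y_pred_all.append(y_pred)
            else:
                fold_reports.append(metrics(confusion(y_true, y_pred, pos_label)))
        if pool:
            c = confusion(np.concatenate(y_true_all), np.concatenate(y_pred_all), pos_label)
            reports.append(metrics(c))
        else:
            table = np.array(
                [[getattr(r, m) for m in METRIC_NAMES] for r in fold_reports]
            ).mean(axis=0)
            reports.append(MetricsReport(*table))
    return CvResult(reports=reports, folds=folds, repetitions=reps, seed=seed)
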