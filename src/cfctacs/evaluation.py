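"""Evaluation design: per-participant splits, cross-validation with
best-validation model selection, metrics and group statistics.

The design mirrors the decoding study: per participant, trials are
partitioned 4:1 into training and test sets (stratified), the training
portion is split into 5 stratified folds, one model is trained per fold, the
model with the best validation accuracy is evaluated once on the held-out
test set, and group-level inference compares per-participant accuracies with
paired t-tests under Benjamini-Hochberg FDR correction, plus one-sample
t-tests against the 50% chance level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _confusion
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "SplitPlan",
    "StatTestResult",
    "CVResult",
    "make_split",
    "cross_validate",
    "compute_metrics",
    "run_ablation",
    "paired_ttest_fdr",
    "one_sample_vs_chance",
]


@dataclass(frozen=True)
class SplitPlan:
    """A per-participant partition: held-out test set + stratified folds."""

    participant: int | str
    test_idx: np.ndarray
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    seed: int

    @property
    def train_idx(self) -> np.ndarray:
        return np.sort(np.concatenate([va for _, va in self.folds]))

    @property
    def hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.sort(self.test_idx).tobytes())
        for tr, va in self.folds:
            h.update(np.sort(tr).tobytes())
            h.update(np.sort(va).tobytes())
        return h.hexdigest()[:16]

    def validate(self, labels: np.ndarray) -> None:
        """Assert disjointness, coverage and stratification."""
        labels = np.asarray(labels)
        n = len(labels)
        train = self.train_idx
        assert len(np.intersect1d(self.test_idx, train)) == 0, (
            "test overlaps training"
        )
        assert len(train) + len(self.test_idx) == n, "indices do not cover data"
        all_val = np.concatenate([va for _, va in self.folds])
        assert len(np.unique(all_val)) == len(all_val), "folds overlap"
        # stratification keeps each class count within one sample of the
        # proportional expectation in every fold
        for cls in np.unique(labels):
            frac = np.mean(labels[train] == cls)
            for _, va in self.folds:
                expect = len(va) * frac
                got = int(np.sum(labels[va] == cls))
                assert abs(got - expect) <= 1.0 + 1e-9, "fold not stratified"


@dataclass(frozen=True)
class StatTestResult:
    """One t-test with its FDR-adjusted p-value."""

    label: str
    t: float
    df: int
    p: float
    p_adj: float
    significant: bool
    alpha: float = 0.05


@dataclass
class CVResult:
    """Cross-validation outcome for one participant and configuration."""

    participant: int | str
    fold_val_acc: list[float]
    fold_val_loss: list[float]
    best_fold: int
    test_accuracy: float
    test_auc: float
    confusion: np.ndarray
    roc: tuple[np.ndarray, np.ndarray]
    split_hash: str
    decoder: object | None = None


def make_split(
    labels: np.ndarray,
    test_fraction: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
    participant: int | str = 0,
) -> SplitPlan:
    """Stratified 4:1 test split followed by a stratified k-fold partition
    of the training portion."""
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to build a split")
    min_train = np.floor(counts * (1 - test_fraction)).min()
    if min_train < n_folds:
        raise ValueError(
            f"too few samples: the smallest class would contribute "
            f"{int(min_train)} training trials but {n_folds} folds are "
            f"required"
        )
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = tuple(
        (train_idx[tr], train_idx[va])
        for tr, va in skf.split(train_idx, labels[train_idx])
    )
    plan = SplitPlan(
        participant=participant,
        test_idx=np.asarray(test_idx),
        folds=folds,
        seed=seed,
    )
    plan.validate(labels)
    return plan


def compute_metrics(proba: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy, ROC curve, trapezoidal AUC and 2x2 confusion matrix.

    ``proba`` is either an (n, 2) probability matrix or an (n,) score for
    the positive class (the larger label).
    """
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC is undefined for a single-class label vector")
    pos = classes[-1]
    y = (labels == pos).astype(int)
    if proba.ndim == 2:
        scores = proba[:, 1]
        pred = proba.argmax(axis=1)
    else:
        scores = proba
        pred = (scores >= 0.5).astype(int)
    accuracy = float((pred == y).mean())
    fpr, tpr, _ = _roc_curve(y, scores)
    roc_auc = float(_auc(fpr, tpr))
    cm = _confusion(y, pred, labels=[0, 1])
    return {
        "accuracy": accuracy,
        "auc": roc_auc,
        "roc": (fpr, tpr),
        "confusion": cm,
    }


def cross_validate(
    decoder_factory,
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    train_config,
    keep_decoder: bool = False,
) -> CVResult:
    """Train one model per fold; evaluate the best-validation model on the
    held-out test set.

    ``decoder_factory(fold_seed)`` must return a fresh trainable model
    exposing ``fit``/``predict_proba``.  Ties in validation accuracy are
    broken by lower validation loss, then by lower fold index.
    """
    from dataclasses import replace as _dc_replace

    y = np.asarray(y)
    classes = np.unique(y)
    y_enc = np.searchsorted(classes, y)
    seeds = np.random.SeedSequence(train_config.seed).generate_state(
        len(plan.folds)
    ) % (2**31)
    fold_acc, fold_loss, models = [], [], []
    for k, (tr, va) in enumerate(plan.folds):
        dec = decoder_factory(int(seeds[k]))
        tc = _dc_replace(train_config, seed=int(seeds[k]))
        dec.fit(X[tr], y_enc[tr], X[va], y_enc[va], tc)
        h = dec.history
        fold_acc.append(h.get("best_val_acc", h["val_acc"][-1]))
        fold_loss.append(h.get("best_val_loss", h["val_loss"][-1]))
        models.append(dec)
    order = sorted(
        range(len(models)),
        key=lambda k: (-fold_acc[k], fold_loss[k], k),
    )
    best = order[0]
    proba = models[best].predict_proba(X[plan.test_idx])
    m = compute_metrics(proba, y_enc[plan.test_idx])
    return CVResult(
        participant=plan.participant,
        fold_val_acc=[float(a) for a in fold_acc],
        fold_val_loss=[float(l) for l in fold_loss],
        best_fold=best,
        test_accuracy=m["accuracy"],
        test_auc=m["auc"],
        confusion=m["confusion"],
        roc=m["roc"],
        split_hash=plan.hash,
        decoder=models[best] if keep_decoder else None,
    )


def run_ablation(results: list[dict]) -> pd.DataFrame:
    """Assemble per-participant, per-configuration results into a report.

    ``results`` rows must carry ``participant``, ``config`` (label),
    ``accuracy`` and ``split_hash``; the paired design is verified by
    requiring identical split hashes across configurations within each
    participant.  Returns a tidy DataFrame with group mean +- SEM attached
    in ``DataFrame.attrs["group"]``.
    """
    df = pd.DataFrame(results)
    required = {"participant", "config", "accuracy", "split_hash"}
    if not required.issubset(df.columns):
        raise ValueError(f"result rows must carry {sorted(required)}")
    for pid, sub in df.groupby("participant"):
        if sub["split_hash"].nunique() != 1:
            raise ValueError(
                f"participant {pid}: configurations use different trial "
                "partitions; the paired design requires identical splits"
            )
    group = (
        df.groupby("config")["accuracy"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    df.attrs["group"] = group
    return df


def paired_ttest_fdr(
    accuracy_by_config: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
) -> list[StatTestResult]:
    """Two-sided paired t-tests with Benjamini-Hochberg correction.

    The BH step-up runs across the whole ``comparisons`` family.  A
    zero-variance difference (e.g. identical vectors) is a contract
    violation and raises instead of returning p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    raw = []
    for a, b in comparisons:
        va = np.asarray(accuracy_by_config[a], dtype=float)
        vb = np.asarray(accuracy_by_config[b], dtype=float)
        if va.shape != vb.shape or va.ndim != 1 or len(va) < 2:
            raise ValueError(f"comparison {a} vs {b}: need paired vectors, n>=2")
        d = va - vb
        if np.allclose(d.std(ddof=1), 0.0):
            raise ValueError(
                f"comparison {a} vs {b}: zero-variance differences, "
                "t is undefined"
            )
        t, p = sps.ttest_rel(va, vb)
        raw.append((f"{a} vs {b}", float(t), len(va) - 1, float(p)))
    reject, p_adj, _, _ = multipletests(
        [r[3] for r in raw], alpha=alpha, method="fdr_bh"
    )
    return [
        StatTestResult(
            label=lab, t=t, df=df, p=p, p_adj=float(pa), significant=bool(rej),
            alpha=alpha,
        )
        for (lab, t, df, p), pa, rej in zip(raw, p_adj, reject)
    ]


def one_sample_vs_chance(
    accuracies: np.ndarray, chance: float = 50.0, alpha: float = 0.05,
    label: str = "vs chance",
) -> StatTestResult:
    """Two-sided one-sample t-test of decoding accuracies against chance."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 1 or len(acc) < 2:
        raise ValueError("need a 1-D accuracy vector with n >= 2")
    if np.allclose(acc.std(ddof=1), 0.0):
        raise ValueError("zero-variance accuracies, t is undefined")
    t, p = sps.ttest_1samp(acc, chance)
    return StatTestResult(
        label=label, t=float(t), df=len(acc) - 1, p=float(p),
        p_adj=float(p), significant=bool(p < alpha), alpha=alpha,
    )
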