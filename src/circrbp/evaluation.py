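"""Classification metrics and the resampled repeated k-fold cross-validation.

Metrics are the standard confusion-matrix quantities — sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), precision Pr = TP/(TP+FP),
accuracy, and Matthews correlation coefficient — plus threshold-free AUC
(rank statistic, ties counted 1/2) and AUCPR (step-wise precision-recall
integration).  A metric whose denominator is zero is reported as NaN (an
explicit "undefined" marker) rather than a silent zero.

The cross-validation scheme matches the positive-unlabeled setting: each
repeat draws a fresh balanced negative sample from the unlabeled cells,
splits the balanced set into label-stratified folds, trains on k-1 folds
and scores the held-out fold.  Held-out positives are (by default) masked
out of the interaction profiles the profile-tower kernel consumes, so a
test label never leaks into the model input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import InteractionMatrix, partition_pairs
from .kernels import PairScores, TrainConfig, init_model, score_pairs, train

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVConfig",
    "confusion",
    "metrics",
    "metric_arrays",
    "auc",
    "aucpr",
    "roc_points",
    "pr_points",
    "score_metrics",
    "cross_validate",
    "CVResult",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    Pr: float
    Acc: float
    MCC: float
    AUC: float = np.nan
    AUCPR: float = np.nan
    threshold: float = 0.5
    counts: ConfusionCounts | None = None
    roc: np.ndarray | None = None  # (fpr, tpr) points
    pr: np.ndarray | None = None  # (recall, precision) points

    def as_dict(self) -> dict[str, float]:
        return {
            "Sn": self.Sn, "Sp": self.Sp, "Pr": self.Pr,
            "Acc": self.Acc, "MCC": self.MCC,
            "AUC": self.AUC, "AUCPR": self.AUCPR,
        }


@dataclass
class CVConfig:
    """Repeated stratified k-fold CV with per-repeat negative resampling."""

    k: int = 5
    repeats: int = 10
    seed: int = 0
    threshold: float = 0.5
    mask_heldout: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def confusion(scores: PairScores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; a pair is called positive iff score > threshold."""
    if scores.labels is None:
        raise ValueError("confusion requires labels")
    y = scores.labels.astype(bool)
    pred = scores.scores > threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & y)),
        TN=int(np.sum(~pred & ~y)),
        FP=int(np.sum(pred & ~y)),
        FN=int(np.sum(~pred & y)),
    )


def metric_arrays(
    TP: np.ndarray, TN: np.ndarray, FP: np.ndarray, FN: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (Sn, Sp, Pr, Acc, MCC); zero denominators yield NaN."""
    TP = np.asarray(TP, dtype=np.float64)
    TN = np.asarray(TN, dtype=np.float64)
    FP = np.asarray(FP, dtype=np.float64)
    FN = np.asarray(FN, dtype=np.float64)

    def _div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        return np.where(den > 0, out, np.nan)

    Sn = _div(TP, TP + FN)
    Sp = _div(TN, TN + FP)
    Pr = _div(TP, TP + FP)
    Acc = _div(TN + TP, TN + FP + TP + FN)
    mcc_den = np.sqrt((TP + FP) * (TN + FN) * (TP + FN) * (TN + FP))
    MCC = _div(TP * TN - FP * FN, mcc_den)
    return Sn, Sp, Pr, Acc, MCC


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Pr, Acc and MCC from a confusion tally."""
    if c.total < 1:
        raise ValueError("metrics require at least one evaluated pair")
    Sn, Sp, Pr, Acc, MCC = (float(v) for v in metric_arrays(c.TP, c.TN, c.FP, c.FN))
    return MetricsReport(Sn=Sn, Sp=Sp, Pr=Pr, Acc=Acc, MCC=MCC, counts=c)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic with ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores, method="average")
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) at every distinct score threshold, descending score."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1.0 - y)[distinct]
    n_pos, n_neg = max(y.sum(), 1.0), max((1.0 - y).sum(), 1.0)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return np.column_stack([fpr, tpr])


def pr_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(recall, precision) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1.0 - y)[distinct]
    n_pos = max(y.sum(), 1.0)
    recall = tps / n_pos
    precision = tps / np.maximum(tps + fps, 1.0)
    return np.column_stack([recall, precision])


def aucpr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated).

    Equivalent to average precision: sum over thresholds of
    (recall_t - recall_{t-1}) * precision_t.
    """
    labels = np.asarray(labels)
    if np.sum(labels == 1) == 0 or np.sum(labels == 0) == 0:
        return float("nan")
    pts = pr_points(scores, labels)
    recall, precision = pts[:, 0], pts[:, 1]
    drec = np.diff(np.r_[0.0, recall])
    return float(np.sum(drec * precision))


def score_metrics(
    scores: PairScores, threshold: float = 0.5, curves: bool = False
) -> MetricsReport:
    """Full metric report (thresholded + threshold-free) for labeled scores."""
    c = confusion(scores, threshold)
    rep = metrics(c)
    rep.threshold = threshold
    rep.AUC = auc(scores.scores, scores.labels)
    rep.AUCPR = aucpr(scores.scores, scores.labels)
    if curves:
        rep.roc = roc_points(scores.scores, scores.labels)
        rep.pr = pr_points(scores.scores, scores.labels)
    return rep


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Per repeat x fold metric rows plus their unweighted mean."""

    folds: pd.DataFrame
    aggregate: dict[str, float]
    config: CVConfig

    def to_tsv(self, path) -> None:
        df = self.folds.copy()
        agg = {"repeat": "aggregate", "fold": "", **self.aggregate}
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Indices of k folds, stratified so each fold is label-balanced."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == label))
        for pos, ix in enumerate(idx):
            folds[pos % k].append(int(ix))
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(
    Y: InteractionMatrix,
    kernel: str = "mfnn",
    layer_sizes: tuple[int, ...] = (64,),
    train_config: TrainConfig | None = None,
    cv: CVConfig | None = None,
) -> CVResult:
    """Repeated k-fold CV with balanced negatives redrawn each repeat.

    Per repeat r: draw |P| unlabeled cells uniformly as negatives, build the
    balanced labeled set, split into k stratified folds; per fold, train the
    kernel on the other k-1 folds and score the held-out fold at the config
    threshold.  For the profile-based kernel, held-out positive cells are
    zeroed in the input matrix so the tested label is not part of the model
    input (``cv.mask_heldout``).  All seeds are derived from ``cv.seed``.
    """
    cv = cv or CVConfig()
    train_config = train_config or TrainConfig()
    part = partition_pairs(Y)
    P = np.array(part.P)
    U = np.array(part.U)
    if len(P) < cv.k:
        raise ValueError("fewer positives than folds")
    master = np.random.SeedSequence(cv.seed)
    repeat_seeds = master.spawn(cv.repeats)
    rows = []
    for r, ss in enumerate(repeat_seeds):
        rng = np.random.default_rng(ss)
        neg_idx = rng.choice(len(U), size=len(P), replace=False)
        pairs = np.vstack([P, U[neg_idx]])
        labels = np.r_[np.ones(len(P)), np.zeros(len(P))]
        folds = _stratified_folds(labels, cv.k, rng)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(labels) and len(np.unique(all_idx)) == len(labels)
        for f_id, test_idx in enumerate(folds):
            test_set = set(map(tuple, pairs[test_idx]))
            train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
            assert not test_set & set(map(tuple, pairs[train_idx]))
            te_labels = labels[test_idx]
            if not (te_labels.min() == 0 and te_labels.max() == 1):
                raise AssertionError("fold lost a class despite stratification")
            Yin = Y.Y.copy()
            if cv.mask_heldout:
                heldout_pos = pairs[test_idx][te_labels == 1]
                Yin[heldout_pos[:, 0], heldout_pos[:, 1]] = 0.0
            fold_seed = int(rng.integers(0, 2**31 - 1))
            model = init_model(
                kernel, Y.n_rbp, Y.n_circ, layer_sizes,
                seed=fold_seed, init_std=train_config.init_std,
                clamp_eps=train_config.clamp_eps,
            )
            tr = PairScores(
                pairs=[tuple(ij) for ij in pairs[train_idx]],
                scores=np.zeros(len(train_idx)),
                labels=labels[train_idx],
            )
            cfg = TrainConfig(**{**vars(train_config), "seed": fold_seed})
            model, _ = train(model, tr, Yin, cfg)
            sc = score_pairs(
                model, [tuple(ij) for ij in pairs[test_idx]], Yin, labels=te_labels
            )
            rep = score_metrics(sc, threshold=cv.threshold)
            rows.append({"repeat": r, "fold": f_id, **rep.as_dict()})
    df = pd.DataFrame(rows)
    metric_cols = ["Sn", "Sp", "Pr", "Acc", "MCC", "AUC", "AUCPR"]
    aggregate = {m: float(np.nanmean(df[m])) for m in metric_cols}
    return CVResult(folds=df, aggregate=aggregate, config=cv)
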