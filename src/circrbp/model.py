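"""Model/Results front end for the interaction-prediction pipeline.

``InteractionModel`` is constructed from an interaction matrix (or an edge
list on disk) plus a kernel choice; ``fit`` trains a single kernel on a
balanced positive/negative sample and returns a :class:`FitResults`, while
``fit_pu`` runs the full bagged positive-unlabeled procedure and
``cross_validate`` the resampled repeated-CV evaluation.  Each returns a
results object with the fitted quantities and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as _data
from . import evaluation as _eval
from . import kernels as _kernels
from . import pu as _pu

__all__ = ["InteractionModel", "FitResults", "PUResults", "CVResults"]


class InteractionModel:
    """A scoring-kernel model of a binary RBP x circRNA interaction matrix.

    Parameters
    ----------
    Y : InteractionMatrix
        The observed 0/1 adjacency (rows = RBPs, columns = circRNAs).
    kernel : {"mfnn", "gmf", "mlp", "neumf"}
        Scoring kernel; the default is the profile-tower cosine kernel.
    layer_sizes : tuple of int
        Tower widths (mfnn) or embedding dim + hidden widths (others).
    """

    def __init__(
        self,
        Y: _data.InteractionMatrix,
        kernel: str = "mfnn",
        layer_sizes: tuple[int, ...] = (64,),
    ):
        if kernel not in _kernels.KERNEL_KINDS:
            raise ValueError(f"unknown kernel {kernel!r}")
        self.Y = Y
        self.kernel = kernel
        self.layer_sizes = tuple(layer_sizes)
        self.partition = _data.partition_pairs(Y)

    @classmethod
    def from_edge_list(
        cls,
        path: str | Path,
        whitelist: str | Path | None = None,
        delimiter: str = "\t",
        header: bool = False,
        **kwargs,
    ) -> "InteractionModel":
        pairs = _data.read_edge_list(path, delimiter=delimiter, header=header)
        if whitelist is not None:
            pairs = _data.filter_by_whitelist(pairs, _data.read_whitelist(whitelist))
        return cls(_data.build_matrix(pairs), **kwargs)

    # -- balanced training sample ------------------------------------------
    def _balanced_sample(self, seed: int) -> _kernels.PairScores:
        rng = np.random.default_rng(seed)
        P = np.array(self.partition.P)
        U = np.array(self.partition.U)
        neg = U[rng.choice(len(U), size=min(len(P), len(U)), replace=False)]
        pairs = np.vstack([P, neg])
        labels = np.r_[np.ones(len(P)), np.zeros(len(neg))]
        return _kernels.PairScores(
            pairs=[tuple(int(v) for v in ij) for ij in pairs],
            scores=np.zeros(len(pairs)),
            labels=labels,
        )

    def fit(
        self, train_config: _kernels.TrainConfig | None = None
    ) -> "FitResults":
        """Train one kernel on positives vs. an equal-size unlabeled sample."""
        cfg = train_config or _kernels.TrainConfig()
        km = _kernels.init_model(
            self.kernel, self.Y.n_rbp, self.Y.n_circ, self.layer_sizes,
            seed=cfg.seed, init_std=cfg.init_std, clamp_eps=cfg.clamp_eps,
        )
        sample = self._balanced_sample(cfg.seed)
        km, trace = _kernels.train(km, sample, self.Y, cfg)
        return FitResults(model=self, kernel_model=km, loss_trace=trace, config=cfg)

    def fit_pu(self, pu_config: _pu.PUConfig | None = None) -> "PUResults":
        """Bagged positive-unlabeled scoring of every unlabeled cell."""
        cfg = pu_config or _pu.PUConfig(kernel=self.kernel, layer_sizes=self.layer_sizes)
        res = _pu.pu_score(self.Y, cfg)
        return PUResults(model=self, result=res, config=cfg)

    def cross_validate(
        self,
        cv: _eval.CVConfig | None = None,
        train_config: _kernels.TrainConfig | None = None,
    ) -> "CVResults":
        """Repeated k-fold CV with negatives redrawn from U each repeat."""
        res = _eval.cross_validate(
            self.Y, kernel=self.kernel, layer_sizes=self.layer_sizes,
            train_config=train_config, cv=cv,
        )
        return CVResults(model=self, result=res)


@dataclass
class FitResults:
    """A trained kernel plus its loss trace."""

    model: InteractionModel
    kernel_model: _kernels.KernelModel
    loss_trace: list[tuple[int, float, float]]
    config: _kernels.TrainConfig

    def predict(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        """Clamped probability scores for explicit (rbp_index, circ_index) cells."""
        return _kernels.score_pairs(self.kernel_model, pairs, self.model.Y).scores

    def predict_matrix(self) -> np.ndarray:
        """Score every cell; returns the full N_r x N_c score matrix F."""
        n_r, n_c = self.model.Y.shape
        pairs = [(i, j) for i in range(n_r) for j in range(n_c)]
        return self.predict(pairs).reshape(n_r, n_c)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loss_trace, columns=["epoch", "train_loss", "val_loss"])

    def save(self, path: str | Path) -> None:
        _kernels.save_checkpoint(self.kernel_model, path, self.config)

    def summary(self) -> str:
        tf = self.trace_frame()
        lines = [
            "Interaction kernel fit",
            "=" * 40,
            f"kernel:        {self.kernel_model.kind}",
            f"layer sizes:   {self.kernel_model.layer_sizes}",
            f"matrix shape:  {self.model.Y.shape} (RBPs x circRNAs)",
            f"positives:     {self.model.partition.n_positive}",
            f"epochs run:    {len(tf)}",
            f"final train loss: {tf.train_loss.iloc[-1]:.6f}",
            f"final val loss:   {tf.val_loss.iloc[-1]:.6f}",
            f"best val loss:    {tf.val_loss.min():.6f}",
        ]
        return "\n".join(lines)


@dataclass
class PUResults:
    """Bagged P-U scores over the unlabeled set."""

    model: InteractionModel
    result: _pu.PUResult
    config: _pu.PUConfig

    def scores_frame(self) -> pd.DataFrame:
        return self.result.to_frame()

    def high_confidence(self, threshold: float | None = None):
        thr = self.config.score_threshold if threshold is None else threshold
        return _pu.high_confidence(self.result, thr)

    def summary(self) -> str:
        hc = self.high_confidence()
        f = self.result.final_scores
        lines = [
            "Positive-unlabeled bagged scoring",
            "=" * 40,
            f"kernel:            {self.config.kernel}",
            f"rounds T:          {self.result.T}",
            f"subsample K:       {self.result.K}",
            f"unlabeled cells:   {len(self.result.pairs)}",
            f"mean times scored: {self.result.times_scored.mean():.3f}",
            f"score range:       [{f.min():.4f}, {f.max():.4f}]",
            f"high-confidence (> {self.config.score_threshold}): {len(hc)} pairs",
        ]
        return "\n".join(lines)


@dataclass
class CVResults:
    """Repeated-CV metric rows and aggregate means."""

    model: InteractionModel
    result: _eval.CVResult

    @property
    def aggregate(self) -> dict[str, float]:
        return self.result.aggregate

    def folds_frame(self) -> pd.DataFrame:
        return self.result.folds

    def summary(self) -> str:
        agg = self.result.aggregate
        cfg = self.result.config
        lines = [
            "Repeated cross-validation",
            "=" * 40,
            f"kernel:   {self.model.kernel}",
            f"scheme:   {cfg.repeats} x CV-{cfg.k}, threshold {cfg.threshold}",
            "",
            f"{'metric':8s}{'mean':>10s}",
        ]
        for m, v in agg.items():
            lines.append(f"{m:8s}{v:10.4f}")
        return "\n".join(lines)
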