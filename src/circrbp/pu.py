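"""Positive-unlabeled bagging over the interaction matrix.

With no verified negatives, a single classifier trained on P vs. all of U
absorbs the hidden positives as noise.  The bagging strategy instead trains
T kernels, each discriminating the positive set P from a fresh random
subsample U_t of the unlabeled set (|U_t| = K, by default K = |P| for a
balanced set), and lets each round score only the unlabeled cells it did
*not* train on.  The final score of an unlabeled cell u is the mean of the
scores from the rounds that left it out:

    F_u = sum_t MFNN_t(u) / t(u),    t(u) = #rounds with u not in U_t.

The round count T is the smallest integer with T * (1 - K/|U|) >= n, which
guarantees every cell is scored about n times in expectation; any cell that
is still unscored after T rounds (possible but rare) gets deterministic
top-up rounds so F_u is defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .data import InteractionMatrix, partition_pairs
from .kernels import PairScores, TrainConfig, init_model, score_pairs, train

__all__ = ["PUConfig", "PUResult", "choose_rounds", "pu_score", "high_confidence"]


@dataclass
class PUConfig:
    """Bagging parameters.

    ``K`` is the per-round unlabeled subsample size (None means K = |P|);
    ``n`` the minimum expected times each unlabeled cell is scored; ``T``
    may be forced (it is validated against the coverage inequality),
    otherwise the minimal admissible T is used.
    """

    T: int | None = None
    K: int | None = None
    n: int = 5
    seed: int = 0
    score_threshold: float = 0.7
    kernel: str = "mfnn"
    layer_sizes: tuple[int, ...] = (64,)
    train_config: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class PUResult:
    """Accumulated bagged scores over the unlabeled set."""

    pairs: list[tuple[int, int]]  # all of U, fixed order
    accumulated: np.ndarray  # sum of per-round scores
    times_scored: np.ndarray  # t(u)
    final_scores: np.ndarray  # accumulated / t(u)
    T: int
    K: int
    rbp_ids: list[str]
    circ_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rbp_id": [self.rbp_ids[i] for i, _ in self.pairs],
                "circ_id": [self.circ_ids[j] for _, j in self.pairs],
                "score": self.final_scores,
                "times_scored": self.times_scored,
            }
        )
        df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def choose_rounds(K: int, U_size: int, n: int, T: int | None = None) -> int:
    """Smallest T with T * (1 - K/U_size) >= n, in exact integer arithmetic.

    If a user-supplied ``T`` is given it is validated against the same
    inequality instead.
    """
    if not (0 <= K < U_size):
        raise ValueError("need 0 <= K < |U| (K = |U| leaves nothing to score)")
    if n < 1:
        raise ValueError("n must be >= 1")
    # T*(1 - K/U) >= n  <=>  T*(U-K) >= n*U
    minimal = -((-n * U_size) // (U_size - K))  # ceil division
    if T is not None:
        if T * (U_size - K) < n * U_size:
            raise ValueError(
                f"T={T} violates the coverage inequality; minimal admissible T is {minimal}"
            )
        return T
    return minimal


def pu_score(Y: InteractionMatrix, cfg: PUConfig | None = None) -> PUResult:
    """Run the bagged P-U scoring loop over all unlabeled cells.

    Each round t: sample U_t (without replacement) from U, train a fresh
    kernel on P (label 1) against U_t (label 0), and score every cell in
    U \\ U_t.  A cell is never scored by a model whose round trained on it.
    Round RNG seeds are spawned from the master seed, so rounds are
    individually reproducible.
    """
    cfg = cfg or PUConfig()
    part = partition_pairs(Y)
    P = np.array(part.P)
    U = np.array(part.U)
    if len(P) < 1:
        raise ValueError("no positive cells")
    K = len(P) if cfg.K is None else cfg.K
    if not (1 <= K <= len(U) - 1):
        raise ValueError("need 1 <= K < |U|")
    if cfg.T is not None:
        # an explicit round count is honoured as-is; coverage of every cell
        # is still guaranteed by the top-up rounds below
        if cfg.T < 1:
            raise ValueError("T must be >= 1")
        T = cfg.T
    else:
        T = choose_rounds(K, len(U), cfg.n)

    master = np.random.SeedSequence(cfg.seed)
    accumulated = np.zeros(len(U))
    times = np.zeros(len(U), dtype=np.int64)

    def run_round(ss: np.random.SeedSequence, score_mask: np.ndarray | None) -> None:
        """One bagging round; ``score_mask`` limits which left-out cells to score."""
        rng = np.random.default_rng(ss)
        ut_idx = rng.choice(len(U), size=K, replace=False)
        in_ut = np.zeros(len(U), dtype=bool)
        in_ut[ut_idx] = True
        to_score = ~in_ut if score_mask is None else (~in_ut & score_mask)
        pairs = np.vstack([P, U[ut_idx]])
        labels = np.r_[np.ones(len(P)), np.zeros(K)]
        round_seed = int(rng.integers(0, 2**31 - 1))
        model = init_model(
            cfg.kernel, Y.n_rbp, Y.n_circ, cfg.layer_sizes,
            seed=round_seed, init_std=cfg.train_config.init_std,
            clamp_eps=cfg.train_config.clamp_eps,
        )
        tr = PairScores(
            pairs=[tuple(ij) for ij in pairs],
            scores=np.zeros(len(pairs)),
            labels=labels,
        )
        tcfg = TrainConfig(**{**vars(cfg.train_config), "seed": round_seed})
        model, _ = train(model, tr, Y, tcfg)
        idx = np.flatnonzero(to_score)
        # leakage guard: nothing we score was in this round's training subsample
        assert not np.any(in_ut[idx])
        sc = score_pairs(model, U[idx], Y)
        accumulated[idx] += sc.scores
        times[idx] += 1

    round_seeds = master.spawn(T)
    for ss in round_seeds:
        run_round(ss, None)
    # deterministic top-up: guarantee t(u) >= 1 for every unlabeled cell
    topup = master.spawn(1)[0]
    extra = 0
    while np.any(times == 0):
        extra += 1
        if extra > 100:
            raise RuntimeError("coverage top-up failed to terminate")
        child = topup.spawn(1)[0]
        topup = child
        run_round(child, times == 0)

    final = accumulated / np.maximum(times, 1)
    return PUResult(
        pairs=[tuple(int(v) for v in ij) for ij in U],
        accumulated=accumulated,
        times_scored=times,
        final_scores=final,
        T=T,
        K=K,
        rbp_ids=Y.rbp_ids,
        circ_ids=Y.circ_ids,
    )


def high_confidence(
    result: PUResult, threshold: float = 0.7
) -> list[tuple[str, str, float, int]]:
    """Pairs with F_u > threshold, sorted by score descending, ranked from 1."""
    df = result.to_frame()
    df = df[df["score"] > threshold].reset_index(drop=True)
    return [
        (row.rbp_id, row.circ_id, float(row.score), rank)
        for rank, row in enumerate(df.itertuples(index=False), start=1)
    ]


def write_manifest(result: PUResult, cfg: PUConfig, path: str | Path) -> None:
    manifest = {
        "T": result.T,
        "K": result.K,
        "n": cfg.n,
        "seed": cfg.seed,
        "kernel": cfg.kernel,
        "layer_sizes": list(cfg.layer_sizes),
        "score_threshold": cfg.score_threshold,
        "train_config": vars(cfg.train_config),
        "n_unlabeled": len(result.pairs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
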