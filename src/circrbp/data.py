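"""Interaction edge lists and the binary RBP x circRNA interaction matrix.

The central object is a dense 0/1 adjacency matrix ``Y`` with RBPs on the
rows and circRNAs on the columns.  ``Y[i, j] = 1`` records an observed
interaction between RBP ``rbp_ids[i]`` and circRNA ``circ_ids[j]``; every
zero cell is *unlabeled*, not a verified non-interaction.  At the scale this
package targets (hundreds of RBPs, ~a hundred circRNAs, ~13% density) a
dense array is both the simplest and the fastest representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionPairList",
    "InteractionMatrix",
    "PairPartition",
    "read_edge_list",
    "write_edge_list",
    "filter_by_whitelist",
    "read_whitelist",
    "build_matrix",
    "matrix_to_pairs",
    "partition_pairs",
    "write_matrix_tsv",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class InteractionPairList:
    """Ordered, deduplicated list of (rbp_id, circ_id) records."""

    records: list[tuple[str, str]]
    provenance: str = ""
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def circ_ids(self) -> set[str]:
        return {c for _, c in self.records}

    def rbp_ids(self) -> set[str]:
        return {r for r, _ in self.records}


@dataclass
class InteractionMatrix:
    """Binary adjacency matrix with row (RBP) and column (circRNA) indices.

    Rows are RBPs, columns are circRNAs; indices are 0-based and IDs are
    kept in sorted order so the mapping is reproducible from the pair list
    alone.
    """

    Y: np.ndarray
    rbp_ids: list[str]
    circ_ids: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix")
        if self.Y.shape != (len(self.rbp_ids), len(self.circ_ids)):
            raise ValueError("Y shape does not match ID list lengths")
        if len(set(self.rbp_ids)) != len(self.rbp_ids):
            raise ValueError("duplicate RBP IDs")
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA IDs")
        vals = np.unique(self.Y)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("Y entries must be 0 or 1")

    @property
    def n_rbp(self) -> int:
        return self.Y.shape[0]

    @property
    def n_circ(self) -> int:
        return self.Y.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape


@dataclass
class PairPartition:
    """Positive set P (cells with y=1) and unlabeled set U (cells with y=0)."""

    P: list[tuple[int, int]]
    U: list[tuple[int, int]]

    @property
    def n_positive(self) -> int:
        return len(self.P)

    @property
    def n_unlabeled(self) -> int:
        return len(self.U)


def _canon(token: str) -> str:
    # case-sensitive on purpose: circBase IDs are lowercase and collisions
    # between differently-cased IDs would be silent data loss
    return token.strip()


def read_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    header: bool = False,
    provenance: str | None = None,
) -> InteractionPairList:
    """Read a two-column (rbp_id, circ_id) edge list.

    Duplicate records (after whitespace canonicalization) are dropped,
    keeping first-seen order; the duplicate count is logged and recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(delimiter)
            if len(parts) < 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}"
                )
            rbp, circ = _canon(parts[0]), _canon(parts[1])
            if not rbp or not circ:
                raise EdgeListError(f"{path}:{lineno}: empty identifier")
            key = (rbp, circ)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            records.append(key)
    if n_dup:
        logger.info("read_edge_list: dropped %d duplicate records", n_dup)
    return InteractionPairList(
        records=records,
        provenance=provenance or str(path),
        n_duplicates=n_dup,
    )


def write_edge_list(
    pairs: InteractionPairList, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rbp, circ in pairs.records:
            fh.write(f"{rbp}{delimiter}{circ}\n")


def read_whitelist(path: str | Path) -> set[str]:
    """Read a one-ID-per-line circRNA whitelist."""
    with open(path, encoding="utf-8") as fh:
        return {_canon(line) for line in fh if line.strip()}


def filter_by_whitelist(
    pairs: InteractionPairList, whitelist: set[str]
) -> InteractionPairList:
    """Keep only records whose circRNA ID is in the whitelist.

    This mirrors the curation step of retaining only interaction pairs whose
    circRNA is recorded in a reference database (circBase-style ID filter).
    Whitelist entries absent from the pair list are ignored.
    """
    if not whitelist:
        raise ValueError("whitelist is empty")
    kept = [rec for rec in pairs.records if rec[1] in whitelist]
    if not kept:
        logger.warning("filter_by_whitelist: no records survived the filter")
    return InteractionPairList(
        records=kept, provenance=pairs.provenance, n_duplicates=pairs.n_duplicates
    )


def build_matrix(pairs: InteractionPairList) -> InteractionMatrix:
    """Build the indexed 0/1 matrix from a pair list.

    Row/column orders are the sorted unique RBP and circRNA IDs, so the
    matrix is a pure function of the record *set*.
    """
    if not pairs.records:
        raise EdgeListError("cannot build a matrix from an empty pair list")
    rbp_ids = sorted({r for r, _ in pairs.records})
    circ_ids = sorted({c for _, c in pairs.records})
    r_index = {r: i for i, r in enumerate(rbp_ids)}
    c_index = {c: j for j, c in enumerate(circ_ids)}
    Y = np.zeros((len(rbp_ids), len(circ_ids)))
    for rbp, circ in pairs.records:
        Y[r_index[rbp], c_index[circ]] = 1.0
    return InteractionMatrix(Y=Y, rbp_ids=rbp_ids, circ_ids=circ_ids)


def matrix_to_pairs(mat: InteractionMatrix) -> InteractionPairList:
    """Inverse of :func:`build_matrix` (up to sorted-ID ordering)."""
    rows, cols = np.nonzero(mat.Y)
    records = [(mat.rbp_ids[i], mat.circ_ids[j]) for i, j in zip(rows, cols)]
    return InteractionPairList(records=records, provenance="matrix")


def partition_pairs(mat: InteractionMatrix) -> PairPartition:
    """Split all N_r x N_c cells into positives P (y=1) and unlabeled U (y=0)."""
    pos = np.argwhere(mat.Y == 1.0)
    neg = np.argwhere(mat.Y == 0.0)
    return PairPartition(
        P=[tuple(int(v) for v in ij) for ij in pos],
        U=[tuple(int(v) for v in ij) for ij in neg],
    )


def write_matrix_tsv(mat: InteractionMatrix, path: str | Path) -> None:
    """Export the matrix as TSV: circRNA IDs as header, RBP IDs first column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rbp_id\t" + "\t".join(mat.circ_ids) + "\n")
        for i, rbp in enumerate(mat.rbp_ids):
            row = "\t".join(str(int(v)) for v in mat.Y[i])
            fh.write(f"{rbp}\t{row}\n")
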