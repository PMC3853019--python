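"""Per-residue feature vectors via the outside sliding window.

Each residue is encoded by concatenating the 2h+1 transformed matrix rows
centred at it (h rows of left context, the residue's own row, h rows of
right context).  Positions beyond the sequence ends contribute all-zero
rows, consistent with zero being the neutral value of the scaled space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import AMINO_ACIDS, MatrixError, ProteinRecord


@dataclass
class WindowConfig:
    """Outside sliding-window size 2h+1 (odd, default 25)."""

    outside_window: int = 25

    def __post_init__(self) -> None:
        if self.outside_window < 1 or self.outside_window % 2 == 0:
            raise ValueError(
                f"outside_window must be an odd integer >= 1, got "
                f"{self.outside_window}"
            )

    @property
    def half(self) -> int:
        return (self.outside_window - 1) // 2


@dataclass
class LabeledDataset:
    """Fixed-length per-residue feature vectors with binary MoRF labels.

    ``provenance`` records (protein_id, 0-based position) for every sample so
    predictions can be mapped back onto sequences.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.provenance):
            raise ValueError("X, y and provenance must have equal lengths")

    def __len__(self) -> int:
        return len(self.y)


def window_features(values: np.ndarray, position: int, config: WindowConfig) -> np.ndarray:
    """Feature vector for one residue: 2h+1 rows centred at ``position``.

    Rows outside [0, N) are all-zero; the result has dimension (2h+1) * 20.
    """
    n = values.shape[0]
    if not 0 <= position < n:
        raise IndexError(f"position {position} out of range for length {n}")
    return window_stack(values, config)[position]


def window_stack(values: np.ndarray, config: WindowConfig) -> np.ndarray:
    """All per-residue window vectors of a matrix, shape (N, (2h+1)*20)."""
    h = config.half
    n, width = values.shape
    padded = np.vstack([
        np.zeros((h, width)), values, np.zeros((h, width))
    ])
    windows = np.lib.stride_tricks.sliding_window_view(padded, (2 * h + 1, width))
    return windows.reshape(n, (2 * h + 1) * width)


def build_dataset(
    proteins: list[ProteinRecord],
    window: WindowConfig = WindowConfig(),
    balance: bool = True,
    negative_ratio: float = 1.0,
    seed: int | None = 0,
) -> LabeledDataset:
    """Assemble a labelled per-residue dataset from annotated proteins.

    One sample per residue, labelled 1 iff it lies in a MoRF interval.  With
    ``balance=True`` all positives are kept and negatives are down-sampled
    uniformly at random (seeded) to ``negative_ratio`` times the positive
    count; when fewer negatives exist, all are kept.

    Every protein must carry a scaled matrix whose row count matches its
    sequence length.
    """
    blocks, labels, prov = [], [], []
    for rec in proteins:
        if rec.matrix is None or len(rec.matrix) != len(rec):
            raise MatrixError(
                f"protein {rec.id!r} lacks a matrix matching its sequence length"
            )
        if rec.matrix.stage != "scaled":
            raise MatrixError(
                f"build_dataset expects scaled matrices, got {rec.matrix.stage!r} "
                f"for {rec.id!r}"
            )
        blocks.append(window_stack(rec.matrix.values, window))
        labels.append(rec.labels())
        prov.extend((rec.id, i) for i in range(len(rec)))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    if balance:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        n_keep = int(round(negative_ratio * len(pos)))
        if n_keep < len(neg):
            neg = rng.choice(neg, size=n_keep, replace=False)
        else:
            import warnings

            warnings.warn(
                f"only {len(neg)} negatives available for requested {n_keep}; "
                "keeping all"
            )
        idx = np.sort(np.concatenate([pos, neg]))
        X, y = X[idx], y[idx]
        prov = [prov[i] for i in idx]
    return LabeledDataset(X, y, prov)
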