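"""Core in-memory containers: protein records and per-residue score matrices.

A score matrix is the N x 20 table of per-position conservation scores for a
protein of N residues, with one column per standard amino acid in PSI-BLAST
header order.  The ``stage`` tag tracks which transformation the values have
been through (``raw`` log-odds straight from the aligner, ``masked`` after
local-mean subtraction, ``filtered`` after clipping at zero, ``smoothed``
after windowed summation, ``scaled`` after division into [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 20 standard amino acids in PSI-BLAST PSSM header order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

STAGES = ("raw", "masked", "filtered", "smoothed", "scaled")


class MatrixError(ValueError):
    """Raised when a score matrix violates its stage or shape contract."""


@dataclass
class ScoreMatrix:
    """An N x 20 per-residue conservation score matrix.

    Parameters
    ----------
    protein_id : str
        Identifier of the owning protein.
    values : numpy.ndarray, shape (N, 20)
        One row per residue, one column per amino acid in ``AMINO_ACIDS``
        order.
    stage : str
        One of ``raw``, ``masked``, ``filtered``, ``smoothed``, ``scaled``.
    """

    protein_id: str
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(AMINO_ACIDS):
            raise MatrixError(
                f"score matrix for {self.protein_id!r} must have 20 columns, "
                f"got shape {self.values.shape}"
            )
        if self.stage not in STAGES:
            raise MatrixError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return self.values.shape[0]

    def validate(self) -> "ScoreMatrix":
        """Check the stage-specific value contract, returning self.

        ``raw`` matrices must hold integers (as emitted by the aligner),
        ``filtered`` matrices must be non-negative and ``scaled`` matrices
        must lie in [-1, 1].  Violations raise :class:`MatrixError`.
        """
        v = self.values
        if self.stage == "raw" and not np.allclose(v, np.round(v)):
            raise MatrixError(f"raw matrix {self.protein_id!r} has non-integer scores")
        if self.stage == "filtered" and (v < 0).any():
            raise MatrixError(f"filtered matrix {self.protein_id!r} has negative values")
        if self.stage == "scaled" and (np.abs(v) > 1 + 1e-12).any():
            raise MatrixError(f"scaled matrix {self.protein_id!r} exceeds [-1, 1]")
        return self

    def with_values(self, values: np.ndarray, stage: str) -> "ScoreMatrix":
        return ScoreMatrix(self.protein_id, values, stage)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Canonicalize 1-based inclusive intervals: sort and merge overlaps.

    Adjacent intervals (e.g. (2,5) and (6,9)) are merged too, since they
    tag a contiguous run of residues.
    """
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class ProteinRecord:
    """A protein sequence with optional MoRF annotations and score matrix.

    MoRF intervals are 1-based inclusive residue coordinates, the convention
    used in annotation files; they are canonicalized (sorted, merged) on
    construction.
    """

    id: str
    sequence: str
    morf_intervals: list[tuple[int, int]] = field(default_factory=list)
    matrix: ScoreMatrix | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        for start, end in self.morf_intervals:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"interval ({start}, {end}) out of range for protein "
                    f"{self.id!r} of length {len(self.sequence)}"
                )
        self.morf_intervals = merge_intervals(self.morf_intervals)
        if self.matrix is not None and len(self.matrix) != len(self.sequence):
            raise MatrixError(
                f"matrix rows ({len(self.matrix)}) != sequence length "
                f"({len(self.sequence)}) for protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def labels(self) -> np.ndarray:
        """Per-residue binary labels: 1 inside a MoRF interval, else 0."""
        y = np.zeros(len(self.sequence), dtype=int)
        for start, end in self.morf_intervals:
            y[start - 1 : end] = 1
        return y

    def with_intervals(self, intervals: list[tuple[int, int]]) -> "ProteinRecord":
        return replace(self, morf_intervals=list(intervals))

    def with_matrix(self, matrix: ScoreMatrix) -> "ProteinRecord":
        return replace(self, matrix=matrix)
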