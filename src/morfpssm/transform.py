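"""PSSM transformations: masking, filtering, smoothing, scaling.

The pipeline converts the absolute log-odds scores of a PSSM into *relative
local conservation* features:

* **masking** subtracts from each score the mean of the scores in a centred
  window of the same column, so a residue's score expresses how conserved it
  is relative to its sequence neighbourhood;
* **filtering** zeroes masked scores that are not above the local mean,
  keeping only above-average conservation;
* **smoothing** replaces each row by the element-wise sum of the rows in a
  centred window (zero rows padded at the termini), propagating conservation
  evidence to neighbouring residues;
* **scaling** divides by a single global divisor and clips into [-1, 1].

The masked value ``Masking_Ci = Ci - mean(C_{i-n} .. C_{i+n})`` with window
size ``2n+1``; at the termini the window is truncated to the positions that
exist and the mean divides by the actual count.  Smoothing pads with zero
rows so the output keeps exactly N rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from sklearn.base import BaseEstimator, TransformerMixin

from .records import MatrixError, ScoreMatrix

ENCODER_MODES = ("raw", "mask_only", "smooth_only", "mfs")


@dataclass
class TransformConfig:
    """Parameters of the matrix transformation pipeline.

    mask_window : odd int, default 25
        Masking window size 2n+1 over which the local mean is taken.
    smooth_window : odd int, default 13
        Smoothing window size 2m+1 over which filtered rows are summed.
    scale_divisor : float or "auto", default "auto"
        Global divisor for scaling into [-1, 1]; "auto" means learn the
        maximum absolute transformed value from the training set.
    encoder_mode : {"raw", "mask_only", "smooth_only", "mfs"}, default "mfs"
        Which ablation of the pipeline to apply.
    """

    mask_window: int = 25
    smooth_window: int = 13
    scale_divisor: float | str = "auto"
    encoder_mode: str = "mfs"

    def __post_init__(self) -> None:
        _check_window(self.mask_window, "mask_window")
        _check_window(self.smooth_window, "smooth_window")
        if self.encoder_mode not in ENCODER_MODES:
            raise ValueError(f"unknown encoder_mode {self.encoder_mode!r}")
        if not isinstance(self.scale_divisor, str) and self.scale_divisor <= 0:
            raise ValueError("scale_divisor must be positive")
        if isinstance(self.scale_divisor, str) and self.scale_divisor != "auto":
            raise ValueError(f"unknown scale_divisor {self.scale_divisor!r}")


def _check_window(window: int, name: str) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 1, got {window}")


def _local_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Column-wise truncated-window local mean (divides by actual count)."""
    n = (window - 1) // 2
    length = values.shape[0]
    csum = np.cumsum(values, axis=0)
    csum = np.vstack([np.zeros((1, values.shape[1])), csum])
    lo = np.clip(np.arange(length) - n, 0, length)
    hi = np.clip(np.arange(length) + n + 1, 0, length)
    window_sum = csum[hi] - csum[lo]
    return window_sum / (hi - lo)[:, None]


def mask(matrix: ScoreMatrix, mask_window: int = 25) -> ScoreMatrix:
    """Subtract the local windowed mean from every score (relative conservation).

    Applied independently to each of the 20 columns; the window includes the
    centre position itself and is truncated at the sequence termini.
    """
    _check_window(mask_window, "mask_window")
    if matrix.stage != "raw":
        raise MatrixError(f"mask expects a raw matrix, got stage {matrix.stage!r}")
    out = matrix.values - _local_mean(matrix.values, mask_window)
    return matrix.with_values(out, "masked")


def filter_positive(matrix: ScoreMatrix) -> ScoreMatrix:
    """Zero out masked scores <= 0, keeping only above-local-mean conservation."""
    if matrix.stage != "masked":
        raise MatrixError(
            f"filter expects a masked matrix, got stage {matrix.stage!r}"
        )
    return matrix.with_values(np.where(matrix.values > 0, matrix.values, 0.0),
                              "filtered")


def smooth(matrix: ScoreMatrix, smooth_window: int = 13) -> ScoreMatrix:
    """Element-wise box sum of rows over a centred window with zero padding.

    With m = (smooth_window - 1)/2, output row i is the sum of rows
    i-m .. i+m where out-of-range rows count as zero; the output keeps
    exactly N rows.
    """
    _check_window(smooth_window, "smooth_window")
    out = convolve1d(
        matrix.values, np.ones(smooth_window), axis=0, mode="constant", cval=0.0
    )
    return matrix.with_values(out, "smoothed")


def scale(matrix: ScoreMatrix, scale_divisor: float) -> ScoreMatrix:
    """Divide every value by a global divisor and clip into [-1, 1]."""
    if isinstance(scale_divisor, str) or scale_divisor <= 0:
        raise ValueError("scale requires a resolved positive divisor")
    out = np.clip(matrix.values / scale_divisor, -1.0, 1.0)
    return matrix.with_values(out, "scaled")


def resolve_scale_divisor(matrices: list[ScoreMatrix]) -> float:
    """Maximum absolute value over a set of transformed matrices (>= tiny eps)."""
    peak = max(float(np.abs(m.values).max()) for m in matrices)
    return peak if peak > 0 else 1.0


def _pre_scale(matrix: ScoreMatrix, config: TransformConfig) -> ScoreMatrix:
    """Apply the configured pipeline up to (but excluding) scaling."""
    if matrix.stage != "raw":
        raise MatrixError(f"encoder expects a raw matrix, got {matrix.stage!r}")
    mode = config.encoder_mode
    if mode == "raw":
        return matrix
    if mode == "mask_only":
        return filter_positive(mask(matrix, config.mask_window))
    if mode == "smooth_only":
        return smooth(matrix, config.smooth_window)
    if mode == "mfs":
        return smooth(
            filter_positive(mask(matrix, config.mask_window)), config.smooth_window
        )
    raise ValueError(f"unknown encoder_mode {mode!r}")


def apply_encoder(matrix: ScoreMatrix, config: TransformConfig) -> ScoreMatrix:
    """Run the configured transformation pipeline ending in a scaled matrix.

    Modes: ``raw`` scales the untouched matrix; ``mask_only`` applies
    mask+filter; ``smooth_only`` smooths the raw matrix directly; ``mfs``
    applies mask, filter and smooth in order.  ``config.scale_divisor`` must
    be resolved to a number (use :class:`PssmEncoder` or
    :func:`resolve_scale_divisor` to learn it from training data).
    """
    if isinstance(config.scale_divisor, str):
        raise ValueError(
            "scale_divisor is unresolved ('auto'); fit a PssmEncoder or pass "
            "a numeric divisor"
        )
    return scale(_pre_scale(matrix, config), config.scale_divisor)


def conservation_profile(matrix: ScoreMatrix) -> np.ndarray:
    """Per-residue local conservation: the sum of each row's 20 scores."""
    return matrix.values.sum(axis=1)


class PssmEncoder(BaseEstimator, TransformerMixin):
    """Transformer from raw score matrices to scaled feature matrices.

    Fitting resolves the global scale divisor as the maximum absolute value
    of the transformed training matrices, so train- and test-time features
    live in the same [-1, 1] space.

    Parameters
    ----------
    mask_window, smooth_window : odd int
        Window sizes of the masking and smoothing steps.
    encoder_mode : {"raw", "mask_only", "smooth_only", "mfs"}
        Pipeline ablation to apply.
    scale_divisor : float or "auto"
        Fixed divisor, or "auto" to learn it at fit time.

    Attributes
    ----------
    scale_divisor_ : float
        The resolved divisor after :meth:`fit`.
    """

    def __init__(
        self,
        mask_window: int = 25,
        smooth_window: int = 13,
        encoder_mode: str = "mfs",
        scale_divisor: float | str = "auto",
    ) -> None:
        self.mask_window = mask_window
        self.smooth_window = smooth_window
        self.encoder_mode = encoder_mode
        self.scale_divisor = scale_divisor

    def _config(self, divisor: float | str | None = None) -> TransformConfig:
        return TransformConfig(
            mask_window=self.mask_window,
            smooth_window=self.smooth_window,
            scale_divisor=self.scale_divisor if divisor is None else divisor,
            encoder_mode=self.encoder_mode,
        )

    def fit(self, X: list[ScoreMatrix], y=None) -> "PssmEncoder":
        config = self._config()
        if isinstance(config.scale_divisor, str):
            if not X:
                raise ValueError("cannot resolve scale_divisor from empty input")
            transformed = [_pre_scale(m, config) for m in X]
            self.scale_divisor_ = resolve_scale_divisor(transformed)
        else:
            self.scale_divisor_ = float(config.scale_divisor)
        return self

    def transform(self, X: list[ScoreMatrix]) -> list[ScoreMatrix]:
        if not hasattr(self, "scale_divisor_"):
            raise ValueError("PssmEncoder is not fitted")
        config = self._config(self.scale_divisor_)
        return [apply_encoder(m, config) for m in X]
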