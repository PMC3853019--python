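"""The MoRF predictor: an RBF-kernel SVM over windowed PSSM features.

:class:`MorfPredictor` is the end-to-end estimator.  ``fit`` takes annotated
protein records that carry raw score matrices, runs the configured encoder
(learning the global scale divisor), builds a class-balanced per-residue
dataset and trains a support-vector classifier.  ``predict`` scores every
residue of a protein with the stored configuration, so train- and test-time
feature spaces are identical by construction.
"""

from __future__ import annotations

import itertools

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .features import LabeledDataset, WindowConfig, build_dataset, window_stack
from .records import ProteinRecord
from .transform import PssmEncoder

#: Coarse grid of the LIBSVM practical guide: c = 2^-5 .. 2^15, g = 2^-15 .. 2^3.
DEFAULT_C_GRID = [2.0**k for k in range(-5, 16, 2)]
DEFAULT_G_GRID = [2.0**k for k in range(-15, 4, 2)]


def grid_search(
    dataset: LabeledDataset,
    c_grid: list[float] | None = None,
    g_grid: list[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (c, g) search by stratified k-fold balanced accuracy.

    Returns the best pair and the full table of mean cross-validated
    balanced accuracies (columns ``c``, ``g``, ``cv_accuracy``).  Ties break
    toward the first grid point in (c, g) iteration order.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("grid search requires both classes present")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    c_grid = DEFAULT_C_GRID if c_grid is None else c_grid
    g_grid = DEFAULT_G_GRID if g_grid is None else g_grid
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for c, g in itertools.product(c_grid, g_grid):
        scores = cross_val_score(
            SVC(C=c, gamma=g, kernel="rbf"),
            dataset.X,
            dataset.y,
            cv=cv,
            scoring="balanced_accuracy",
        )
        rows.append({"c": c, "g": g, "cv_accuracy": float(scores.mean())})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_accuracy"].idxmax()]
    return float(best["c"]), float(best["g"]), table


class MorfPredictor(BaseEstimator, ClassifierMixin):
    """Per-residue MoRF classifier over transformed PSSM windows.

    Parameters
    ----------
    mask_window, smooth_window, outside_window : odd int
        Window sizes of the masking, smoothing and feature-extraction steps
        (defaults 25, 13, 25).
    encoder_mode : {"raw", "mask_only", "smooth_only", "mfs"}
        Matrix transformation ablation; "mfs" is the full
        mask-filter-smooth pipeline.
    C, gamma : float
        RBF-SVM capacity and kernel width (tune with :func:`grid_search`).
    balance : bool
        Down-sample negatives at fit time (all positives kept).
    negative_ratio : float
        Negatives kept per positive when balancing (default 1.0).
    random_state : int
        Seed for negative down-sampling.

    Attributes
    ----------
    encoder_ : PssmEncoder
        Fitted encoder holding the resolved ``scale_divisor_``.
    svm_ : sklearn.svm.SVC
        The trained classifier.
    threshold_ : float
        Decision threshold on the signed margin for binary calls (0.0).
    n_features_in_ : int
        Dimension of the per-residue feature vectors, (2h+1) * 20.
    """

    def __init__(
        self,
        mask_window: int = 25,
        smooth_window: int = 13,
        outside_window: int = 25,
        encoder_mode: str = "mfs",
        C: float = 1.0,
        gamma: float | str = "scale",
        balance: bool = True,
        negative_ratio: float = 1.0,
        random_state: int = 0,
    ) -> None:
        self.mask_window = mask_window
        self.smooth_window = smooth_window
        self.outside_window = outside_window
        self.encoder_mode = encoder_mode
        self.C = C
        self.gamma = gamma
        self.balance = balance
        self.negative_ratio = negative_ratio
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def build_training_dataset(self, proteins: list[ProteinRecord]) -> LabeledDataset:
        """Encode proteins and assemble the (balanced) training dataset.

        Fits the encoder as a side effect; exposed so grid search can reuse
        the exact dataset the final model trains on.
        """
        self.encoder_ = PssmEncoder(
            mask_window=self.mask_window,
            smooth_window=self.smooth_window,
            encoder_mode=self.encoder_mode,
        )
        raw = [p.matrix for p in proteins]
        if any(m is None for m in raw):
            raise ValueError("every training protein needs a raw score matrix")
        scaled = self.encoder_.fit_transform(raw)
        encoded = [p.with_matrix(m) for p, m in zip(proteins, scaled)]
        return build_dataset(
            encoded,
            window=WindowConfig(self.outside_window),
            balance=self.balance,
            negative_ratio=self.negative_ratio,
            seed=self.random_state,
        )

    def fit(
        self, X: list[ProteinRecord], y=None, dataset: LabeledDataset | None = None
    ) -> "MorfPredictor":
        """Train on annotated proteins carrying raw matrices.

        ``y`` is ignored (labels come from the records' MoRF intervals); an
        already-built ``dataset`` may be passed to skip re-encoding.
        """
        if dataset is None:
            dataset = self.build_training_dataset(X)
        if len(np.unique(dataset.y)) < 2:
            raise ValueError("training requires both MoRF and non-MoRF samples")
        self.svm_ = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
        self.svm_.fit(dataset.X, dataset.y)
        self.classes_ = self.svm_.classes_
        self.threshold_ = 0.0
        self.n_features_in_ = dataset.X.shape[1]
        self.n_training_samples_ = len(dataset)
        return self

    # -- prediction --------------------------------------------------------

    def _featurize(self, protein: ProteinRecord) -> np.ndarray:
        if not hasattr(self, "svm_"):
            raise ValueError("MorfPredictor is not fitted")
        if protein.matrix is None or len(protein.matrix) != len(protein):
            raise ValueError(
                f"protein {protein.id!r} lacks a raw matrix matching its length"
            )
        (scaled,) = self.encoder_.transform([protein.matrix])
        return window_stack(scaled.values, WindowConfig(self.outside_window))

    def decision_function(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        """Signed per-residue margins, one array per protein in input order."""
        if not hasattr(self, "svm_"):
            raise ValueError("MorfPredictor is not fitted")
        return [self.svm_.decision_function(self._featurize(p)) for p in X]

    def predict(self, X: list[ProteinRecord]) -> list[np.ndarray]:
        """Binary per-residue calls: score > ``threshold_``."""
        return [
            (scores > self.threshold_).astype(int)
            for scores in self.decision_function(X)
        ]

    def predict_residues(self, X: list[ProteinRecord]) -> pd.DataFrame:
        """Tidy per-residue predictions: protein_id, position (1-based),
        residue, score, call."""
        frames = []
        for protein, scores in zip(X, self.decision_function(X)):
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": protein.id,
                        "position": np.arange(1, len(protein) + 1),
                        "residue": list(protein.sequence),
                        "score": scores,
                        "call": (scores > self.threshold_).astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist the fitted estimator (joblib)."""
        if not hasattr(self, "svm_"):
            raise ValueError("cannot save an unfitted MorfPredictor")
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MorfPredictor":
        model = joblib.load(path)
        if not isinstance(model, MorfPredictor):
            raise TypeError(f"{path} does not contain a MorfPredictor")
        return model
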