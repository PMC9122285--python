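"""Point-environment baseline: a random forest on per-occurrence env vectors.

The comparison model for the convolutional SDM sees only the point value of
each environmental raster at the occurrence location (no spatial context).
The default classifier is a random forest of 100 trees with maximum depth 10
(other parameters at their library defaults), whose per-species relative
probabilities serve directly as ranking and AUC scores.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .rasters import CoverageError

__all__ = ["baseline_train_predict", "BaselineResult"]


class BaselineResult:
    """Fitted baseline with probabilities aligned to the full species index."""

    def __init__(self, classifier: RandomForestClassifier, n_species: int):
        self.classifier = classifier
        self.n_species = n_species

    def predict_proba(self, env_vectors: np.ndarray) -> np.ndarray:
        """(n, S) relative probabilities; unseen species get probability 0."""
        x = _check_no_missing(env_vectors, "prediction")
        raw = self.classifier.predict_proba(x)
        out = np.zeros((len(x), self.n_species))
        out[:, self.classifier.classes_.astype(int)] = raw
        return out


def _check_no_missing(env_vectors: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(env_vectors, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{what} env vectors must be 2D (n, n_rasters)")
    if np.isnan(x).any():
        raise CoverageError(
            f"{what} env vectors contain missing values; remove occurrences "
            "outside raster coverage upstream"
        )
    return x


def baseline_train_predict(
    env_vectors: np.ndarray,
    species_labels: np.ndarray,
    eval_env_vectors: np.ndarray,
    n_species: int,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int = 10,
) -> tuple[np.ndarray, BaselineResult]:
    """Train the point-value baseline and score evaluation occurrences.

    Returns the (n_eval, n_species) probability matrix and the fitted model.
    Missing values on either side raise :class:`~convsdm.rasters.CoverageError`.
    """
    x_tr = _check_no_missing(env_vectors, "training")
    y = np.asarray(species_labels, dtype=int)
    if len(x_tr) != len(y):
        raise ValueError("env vectors and labels must align")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    clf.fit(x_tr, y)
    result = BaselineResult(clf, n_species)
    return result.predict_proba(eval_env_vectors), result
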