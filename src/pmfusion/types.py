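"""Shared in-memory containers used by every module of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NonFiniteInputError, SingleClassError, ViewMismatchError

__all__ = ["FeatureView", "CohortBundle", "as_labels"]


def as_labels(values) -> np.ndarray:
    """Validate and coerce a label vector to an int array in {+1, -1}.

    +1 marks the presence of pathological myopia, -1 its absence.
    Raises :class:`SingleClassError` unless both classes are present.
    """
    y = np.asarray(values)
    y = y.astype(int)
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be +1 or -1")
    if len(np.unique(y)) < 2:
        raise SingleClassError("label vector contains a single class")
    return y


@dataclass
class FeatureView:
    """One modality's subject-by-feature matrix plus its [0,1] scaler.

    ``matrix`` holds raw values; ``fit_scaling`` learns per-feature min/max
    on a training subset and ``scaled`` applies them with clipping, so test
    subjects never leak into the scaling parameters.
    """

    source_id: str
    subject_ids: list
    matrix: np.ndarray
    feature_names: list = field(default_factory=list)
    scale_min: np.ndarray | None = None
    scale_max: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.subject_ids) != self.matrix.shape[0]:
            raise ViewMismatchError(
                f"{len(self.subject_ids)} subject ids for "
                f"{self.matrix.shape[0]} rows in view {self.source_id!r}"
            )
        if not self.feature_names:
            self.feature_names = [
                f"{self.source_id}_{j}" for j in range(self.matrix.shape[1])
            ]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def fit_scaling(self, rows=None) -> "FeatureView":
        """Fit per-feature min/max on ``rows`` (default: all subjects)."""
        sub = self.matrix if rows is None else self.matrix[np.asarray(rows)]
        if not np.isfinite(sub).all():
            raise NonFiniteInputError(
                f"non-finite values in view {self.source_id!r}"
            )
        self.scale_min = sub.min(axis=0)
        self.scale_max = sub.max(axis=0)
        return self

    def scaled(self, rows=None) -> np.ndarray:
        """Min-max scale to [0,1] with clipping; constant features map to 0."""
        if self.scale_min is None or self.scale_max is None:
            raise ValueError("call fit_scaling before scaled")
        sub = self.matrix if rows is None else self.matrix[np.asarray(rows)]
        span = self.scale_max - self.scale_min
        out = np.zeros_like(sub, dtype=float)
        ok = span > 0
        out[:, ok] = (sub[:, ok] - self.scale_min[ok]) / span[ok]
        return np.clip(out, 0.0, 1.0)

    def subset(self, rows) -> "FeatureView":
        """A new view over a row subset, dropping any fitted scaler."""
        rows = np.asarray(rows)
        return FeatureView(
            source_id=self.source_id,
            subject_ids=[self.subject_ids[i] for i in rows],
            matrix=self.matrix[rows].copy(),
            feature_names=list(self.feature_names),
        )


@dataclass
class CohortBundle:
    """Subjects matched across modalities with labels and provenance.

    ``views`` maps modality tags (``"D"`` demographic, ``"G"`` genotype,
    ``"I"`` image bag-of-words) to :class:`FeatureView` objects aligned to
    ``subject_ids``.
    """

    subject_ids: list
    labels: np.ndarray
    views: dict[str, FeatureView]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = as_labels(self.labels)
        n = len(self.subject_ids)
        if len(self.labels) != n:
            raise ViewMismatchError("labels and subject_ids differ in length")
        for tag, view in self.views.items():
            if list(view.subject_ids) != list(self.subject_ids):
                raise ViewMismatchError(
                    f"view {tag!r} is not aligned to the bundle subject order"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels == 1))
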