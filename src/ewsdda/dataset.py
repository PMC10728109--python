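"""Omics dataset container shared by every pipeline stage.

A dataset is a positive-valued feature-by-sample matrix plus per-sample
metadata: an *ordered* class label (disease stage or time point), and
optionally a subject identifier (for paired longitudinal designs), a
model/control arm, and survival annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsDataset", "DatasetError"]


class DatasetError(ValueError):
    """Raised for inconsistent or malformed dataset inputs."""


@dataclass
class OmicsDataset:
    """Feature x sample matrix with ordered class labels.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique feature (gene / metabolite) names; rows of ``values``.
    sample_ids : sequence of str
        Unique sample names; columns of ``values``.
    values : ndarray of shape (n_features, n_samples)
        Non-negative measurements.  NaN marks a missing entry and is only
        permitted before preprocessing.
    class_of : mapping sample -> class label
        Every sample must carry a label from ``class_order``.
    class_order : sequence of str
        The ordered stage / time-point labels (ordering is semantic, e.g.
        normal < I < II < III < IV, and is never inferred from sorting).
    subject_of : mapping sample -> subject id, optional
        Pairs samples across time points in longitudinal designs.
    arm_of : mapping sample -> {"model", "control"}, optional
    survival : mapping sample -> (time, event), optional
        Survival time (positive) and event indicator (0/1).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    class_of: dict[str, str]
    class_order: list[str]
    subject_of: dict[str, str] | None = None
    arm_of: dict[str, str] | None = None
    survival: dict[str, tuple[float, int]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.class_order = list(self.class_order)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DatasetError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DatasetError("duplicate sample IDs")
        if len(set(self.class_order)) != len(self.class_order):
            raise DatasetError("duplicate class labels in class_order")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DatasetError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        missing_meta = [s for s in self.sample_ids if s not in self.class_of]
        if missing_meta:
            raise DatasetError(f"samples without class labels: {missing_meta[:5]}")
        unknown = sorted({self.class_of[s] for s in self.sample_ids} - set(self.class_order))
        if unknown:
            raise DatasetError(f"class labels outside class_order: {unknown}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise DatasetError("negative values are not permitted")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> np.ndarray:
        """Per-column class labels, aligned with ``sample_ids``."""
        return np.array([self.class_of[s] for s in self.sample_ids])

    def class_sizes(self) -> dict[str, int]:
        labels = self.classes
        return {c: int(np.sum(labels == c)) for c in self.class_order}

    def class_mask(self, label: str) -> np.ndarray:
        return self.classes == label

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def is_strictly_positive(self) -> bool:
        return bool(np.all(np.isfinite(self.values)) and np.all(self.values > 0))

    # ------------------------------------------------------------------
    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "OmicsDataset":
        """Return a dataset restricted to the given samples (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            keep = [s for s, k in zip(self.sample_ids, keep) if k]
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        sub = {s: self.class_of[s] for s in keep}
        return OmicsDataset(
            feature_ids=self.feature_ids,
            sample_ids=keep,
            values=self.values[:, idx],
            class_of=sub,
            class_order=[c for c in self.class_order if c in set(sub.values())],
            subject_of={s: self.subject_of[s] for s in keep} if self.subject_of else None,
            arm_of={s: self.arm_of[s] for s in keep} if self.arm_of else None,
            survival={s: self.survival[s] for s in keep if s in self.survival}
            if self.survival
            else None,
            meta=dict(self.meta),
        )

    def subset_features(self, keep: Sequence[str]) -> "OmicsDataset":
        keep = list(keep)
        idx = [self.feature_ids.index(f) for f in keep]
        return replace(self, feature_ids=keep, values=self.values[idx, :])

    def with_values(self, values: np.ndarray) -> "OmicsDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def model_arm(self) -> "OmicsDataset":
        if self.arm_of is None:
            raise DatasetError("dataset has no model/control arm annotation")
        return self.subset_samples([s for s in self.sample_ids if self.arm_of[s] == "model"])

    def control_arm(self) -> "OmicsDataset":
        if self.arm_of is None:
            raise DatasetError("dataset has no model/control arm annotation")
        return self.subset_samples([s for s in self.sample_ids if self.arm_of[s] == "control"])

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        rows = {}
        for s in self.sample_ids:
            row: dict[str, object] = {"class": self.class_of[s]}
            if self.subject_of is not None:
                row["subject_id"] = self.subject_of.get(s, "")
            if self.arm_of is not None:
                row["arm"] = self.arm_of.get(s, "")
            if self.survival is not None and s in self.survival:
                t, e = self.survival[s]
                row["survival_time"] = t
                row["event"] = int(e)
            rows[s] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "sample_id"
        return df
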