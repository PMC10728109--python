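"""Per-group data-cleaning rules applied before any ratio computation.

Two rules, applied per class group:

* a feature that is zero in *every* sample of at least one group is excluded;
* a missing value of feature f in group k is imputed as 10% of the minimum
  nonzero value of f within group k.

Exclusion runs before imputation so the group minimum used by the imputation
rule is always defined.  A final strict-positivity gate replaces residual
sporadic zeros (a zero for a feature that is positive elsewhere in every
group) by the same 10%-of-group-minimum rule, because ratio denominators
must be positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import OmicsDataset

logger = logging.getLogger(__name__)

__all__ = ["PreprocessReport", "exclude_all_zero", "impute_missing", "preprocess"]


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    imputed_count: int = 0
    zero_replaced_count: int = 0
    excluded_features: list[str] = field(default_factory=list)
    per_group_min_nonzero: dict[tuple[str, str], float] = field(default_factory=dict)

    def merged_with(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            imputed_count=self.imputed_count + other.imputed_count,
            zero_replaced_count=self.zero_replaced_count + other.zero_replaced_count,
            excluded_features=self.excluded_features + other.excluded_features,
            per_group_min_nonzero={**self.per_group_min_nonzero, **other.per_group_min_nonzero},
        )

    def to_dict(self) -> dict:
        return {
            "imputed_count": self.imputed_count,
            "zero_replaced_count": self.zero_replaced_count,
            "excluded_features": list(self.excluded_features),
            "per_group_min_nonzero": {
                f"{f}|{c}": v for (f, c), v in self.per_group_min_nonzero.items()
            },
        }


def exclude_all_zero(ds: OmicsDataset) -> tuple[OmicsDataset, PreprocessReport]:
    """Drop features whose observed values are all zero within >= 1 class.

    Missing entries are ignored when judging "all zero": a group with only
    NaNs and zeros counts as all-zero (it has no nonzero observation).
    """
    report = PreprocessReport()
    vals = ds.values
    drop = np.zeros(ds.n_features, dtype=bool)
    for c in ds.class_order:
        block = vals[:, ds.class_mask(c)]
        with np.errstate(invalid="ignore"):
            any_nonzero = np.nansum(block > 0, axis=1) > 0
        drop |= ~any_nonzero
    report.excluded_features = [f for f, d in zip(ds.feature_ids, drop) if d]
    if drop.all():
        raise PreprocessError("all features excluded by the all-zero-in-a-group rule")
    if report.excluded_features:
        logger.info(
            "excluded %d feature(s) all-zero in at least one group: %s",
            len(report.excluded_features),
            report.excluded_features,
        )
        ds = ds.subset_features([f for f, d in zip(ds.feature_ids, drop) if not d])
    return ds, report


def impute_missing(ds: OmicsDataset) -> tuple[OmicsDataset, PreprocessReport]:
    """Replace missing entries by 10% of the group's minimum nonzero value.

    Raises if a feature has a missing entry in a group with no positive
    observation (run :func:`exclude_all_zero` first).
    """
    report = PreprocessReport()
    vals = ds.values.copy()
    for c in ds.class_order:
        cmask = ds.class_mask(c)
        block = vals[:, cmask]
        nan_rows = np.flatnonzero(np.isnan(block).any(axis=1))
        for fi in nan_rows:
            row = block[fi]
            positive = row[np.isfinite(row) & (row > 0)]
            if positive.size == 0:
                raise PreprocessError(
                    f"cannot impute feature {ds.feature_ids[fi]!r} in group {c!r}: "
                    "no positive observed value (feature should have been excluded)"
                )
            fill = 0.1 * float(positive.min())
            n_missing = int(np.isnan(row).sum())
            row[np.isnan(row)] = fill
            block[fi] = row
            report.imputed_count += n_missing
            report.per_group_min_nonzero[(ds.feature_ids[fi], c)] = float(positive.min())
        vals[:, cmask] = block
    if report.imputed_count == 0:
        return ds, report
    logger.info("imputed %d missing entr(ies) with 10%% of group minimum nonzero", report.imputed_count)
    return ds.with_values(vals), report


def _positivity_gate(ds: OmicsDataset) -> tuple[OmicsDataset, PreprocessReport]:
    """Replace residual exact zeros via the 10%-of-group-minimum rule."""
    report = PreprocessReport()
    if not np.any(ds.values == 0):
        return ds, report
    vals = ds.values.copy()
    for c in ds.class_order:
        cmask = ds.class_mask(c)
        block = vals[:, cmask]
        zero_rows = np.flatnonzero((block == 0).any(axis=1))
        for fi in zero_rows:
            row = block[fi]
            positive = row[row > 0]
            if positive.size == 0:  # pragma: no cover - excluded upstream
                raise PreprocessError(
                    f"feature {ds.feature_ids[fi]!r} all-zero in group {c!r} at positivity gate"
                )
            fill = 0.1 * float(positive.min())
            report.zero_replaced_count += int((row == 0).sum())
            row[row == 0] = fill
            block[fi] = row
        vals[:, cmask] = block
    logger.info("positivity gate replaced %d residual zero(s)", report.zero_replaced_count)
    return ds.with_values(vals), report


def preprocess(ds: OmicsDataset) -> tuple[OmicsDataset, PreprocessReport]:
    """Full cleaning chain: exclude all-zero groups, impute missing values,
    then enforce strict positivity.  Returns the cleaned dataset and a
    merged report."""
    ds, rep1 = exclude_all_zero(ds)
    ds, rep2 = impute_missing(ds)
    ds, rep3 = _positivity_gate(ds)
    report = rep1.merged_with(rep2).merged_with(rep3)
    if not ds.is_strictly_positive():
        raise PreprocessError("matrix not strictly positive after preprocessing")
    return ds, report
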