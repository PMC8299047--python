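"""Two-stage abundance normalization and the ranked relative-abundance map.

Stage one removes per-sample technical offsets by log2 transformation and
median centering within each sample.  Stage two removes residual inter-batch
offsets by subtracting, within each batch, the median abundance of a set of
low-variability "housekeeping-like" reference proteins — proteins detected in
every sample of the cohort whose per-batch coefficient of variation stays
below a threshold (default 60%).  The normalized matrix is summarized as a
per-protein median relative abundance with a dense detection count and rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Protein x sample quantification values with batch labels.

    ``values`` is indexed by protein id with sample-id columns; missing
    (not-detected) entries are NaN.  ``batches`` maps each sample id to its
    batch label.  ``scale`` records whether values are linear intensities or
    log2-transformed.
    """

    values: pd.DataFrame
    batches: pd.Series
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        self.batches = pd.Series(self.batches)
        missing = [s for s in self.values.columns if s not in self.batches.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")
        self.batches = self.batches.loc[self.values.columns]
        if self.scale == "linear":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("linear-scale matrix contains negative values")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_batch(self, batch) -> list[str]:
        return list(self.batches.index[self.batches == batch])

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.batches.copy(), self.scale)


@dataclass
class ReferenceSet:
    """Reference proteins for inter-batch correction, with an audit CV table."""

    protein_ids: list[str]
    per_batch_cv: pd.DataFrame  # protein x batch, percent units

    def __len__(self) -> int:
        return len(self.protein_ids)


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sd with n-1).

    Defined for >= 2 values with positive mean; NaNs are not tolerated here
    (filter upstream).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("cv requires at least two values")
    if np.isnan(arr).any():
        raise ValueError("cv input contains NaN")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"cv undefined for non-positive mean ({mean})")
    return 100.0 * arr.std(ddof=1) / mean


def log2_median_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform and subtract each sample's median of detected values.

    Idempotent on the log2 scale: re-centering an already centered matrix
    leaves it unchanged.  Missing entries stay missing.
    """
    vals = matrix.values
    if matrix.scale == "linear":
        bad = (vals <= 0) & vals.notna()
        if bad.any().any():
            prot = bad.any(axis=1).idxmax()
            samp = bad.loc[prot].idxmax()
            raise ValueError(
                f"non-positive value at protein {prot!r}, sample {samp!r}; "
                "linear intensities must be > 0 to log2-transform")
        logv = np.log2(vals)
    else:
        logv = vals
    centered = logv - logv.median(axis=0, skipna=True)
    return AbundanceMatrix(centered, matrix.batches, scale="log2")


def per_batch_cv_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein, per-batch CV (%) on linear-scale detected values.

    Proteins with fewer than two detected values in a batch get NaN there.
    """
    if matrix.scale != "linear":
        raise ValueError("CV is computed on the linear scale")
    out = {}
    for batch in pd.unique(matrix.batches):
        sub = matrix.values[matrix.samples_in_batch(batch)]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = 100.0 * sd / mean
        col[(n < 2) | (mean <= 0)] = np.nan
        out[batch] = col
    return pd.DataFrame(out)


def select_reference_proteins(matrix: AbundanceMatrix,
                              cv_threshold: float = 60.0,
                              detection_fraction: float = 1.0) -> ReferenceSet:
    """Proteins detected everywhere with per-batch CV below threshold.

    Both criteria follow the reference-protein definition: detected in (by
    default) 100% of the samples of the whole cohort, and CV strictly below
    ``cv_threshold`` percent within every batch, computed on the linear scale.
    """
    if matrix.scale != "linear":
        raise ValueError("reference selection operates on the linear-scale matrix")
    detected_frac = matrix.values.notna().mean(axis=1)
    cv_table = per_batch_cv_table(matrix)
    ok_detect = detected_frac >= detection_fraction
    ok_cv = (cv_table < cv_threshold).all(axis=1) & cv_table.notna().all(axis=1)
    selected = matrix.values.index[ok_detect & ok_cv]
    if len(selected) == 0:
        warnings.warn("no protein qualifies as reference; inter-batch "
                      "correction will be a no-op", stacklevel=2)
    return ReferenceSet(list(selected), cv_table.loc[selected])


def batch_reference_offsets(matrix: AbundanceMatrix,
                            refset: ReferenceSet) -> pd.Series:
    """Per-batch median of reference-protein log2 abundances."""
    if matrix.scale != "log2":
        raise ValueError("offsets are computed on the log2-centered matrix")
    offsets = {}
    for batch in pd.unique(matrix.batches):
        block = matrix.values.loc[refset.protein_ids,
                                  matrix.samples_in_batch(batch)]
        offsets[batch] = float(np.nanmedian(block.to_numpy()))
    return pd.Series(offsets, name="batch_offset")


def interbatch_correct(matrix: AbundanceMatrix,
                       refset: ReferenceSet) -> AbundanceMatrix:
    """Subtract each batch's reference-protein median from all its values.

    After correction the median over (reference proteins x batch samples) is
    zero in every batch, aligning batches on the reference set.  An empty
    reference set passes the matrix through unchanged (warned).
    """
    if len(refset) == 0:
        warnings.warn("empty reference set: inter-batch correction skipped",
                      stacklevel=2)
        return matrix.copy()
    offsets = batch_reference_offsets(matrix, refset)
    corrected = matrix.values.copy()
    for batch, off in offsets.items():
        cols = matrix.samples_in_batch(batch)
        corrected[cols] = corrected[cols] - off
    logger.info("inter-batch correction with %d reference proteins; offsets: %s",
                len(refset), offsets.to_dict())
    return AbundanceMatrix(corrected, matrix.batches, scale="log2")


def relative_abundance(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein median over detected samples, detection count, and rank.

    Rank 1 is the most abundant protein; ties are broken by protein id so the
    ranking is a reproducible permutation.
    """
    med = matrix.values.median(axis=1, skipna=True)
    n_det = matrix.values.notna().sum(axis=1)
    out = pd.DataFrame({"median_abundance": med, "n_samples_detected": n_det})
    # descending abundance, id as tie-break; never-detected proteins sink last
    order_idx = sorted(
        out.index,
        key=lambda i: (bool(np.isnan(med[i])),
                       -(med[i] if not np.isnan(med[i]) else 0.0), str(i)))
    out["rank"] = pd.Series(np.arange(1, len(out) + 1), index=order_idx)
    return out


class NormalizationResult(NamedTuple):
    centered: AbundanceMatrix
    refset: ReferenceSet
    offsets: pd.Series
    corrected: AbundanceMatrix
    abundance_map: pd.DataFrame


def normalize_pipeline(matrix: AbundanceMatrix,
                       cv_threshold: float = 60.0,
                       detection_fraction: float = 1.0) -> NormalizationResult:
    """center -> select references -> inter-batch correct -> abundance map."""
    centered = log2_median_center(matrix)
    refset = select_reference_proteins(matrix, cv_threshold, detection_fraction)
    if len(refset):
        offsets = batch_reference_offsets(centered, refset)
    else:
        offsets = pd.Series(dtype=float)
    corrected = interbatch_correct(centered, refset)
    return NormalizationResult(centered, refset, offsets, corrected,
                               relative_abundance(corrected))
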