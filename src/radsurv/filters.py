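"""Feature filtering and transformation.

The cohort-level filters mirror good radiomics practice: an erosion-based
test-retest robustness filter (ICC(2,1) > 0.85, strict), a near-zero-variance
filter, and center scaling to zero mean / unit (sample) SD so that distance
measurements are comparable across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "icc_2_1",
    "RobustnessReport",
    "icc_robustness_filter",
    "near_zero_variance_filter",
    "center_scale",
    "apply_center_scale",
    "ScalingParams",
]


def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``x`` and ``y`` are the two measurement sets (original and eroded
    extractions) over the same subjects.  Returns NaN when the between-subject
    variance is degenerate (constant feature).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D arrays")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    data = np.stack([x, y], axis=1)  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1  # k - 1
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (ss_rows == 0 and ss_err == 0 and ss_cols == 0):
        return float("nan")
    # clip numerical noise outside the ICC range
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


@dataclass
class RobustnessReport:
    table: pd.DataFrame  # columns: feature, icc, kept
    n_pairs: int
    threshold: float

    @property
    def kept(self) -> list[str]:
        return self.table.loc[self.table.kept, "feature"].tolist()

    @property
    def dropped(self) -> list[str]:
        return self.table.loc[~self.table.kept, "feature"].tolist()


def icc_robustness_filter(
    original: pd.DataFrame,
    eroded: pd.DataFrame,
    threshold: float = 0.85,
) -> RobustnessReport:
    """Per-feature ICC(2,1) between original and eroded extractions.

    Rows must be matched lesions (aligned on the shared index).  A feature is
    kept iff ICC > threshold (strict).  Zero-variance features have an
    undefined ICC and are dropped.
    """
    common = original.index.intersection(eroded.index)
    if len(common) < len(original) or len(common) < len(eroded):
        original = original.loc[common]
        eroded = eroded.loc[common]
    if len(common) < 10:
        warnings.warn(
            f"only {len(common)} matched lesions for the robustness filter",
            stacklevel=2,
        )
    feats = [c for c in original.columns if c in eroded.columns]
    rows = []
    for f in feats:
        icc = icc_2_1(original[f].to_numpy(), eroded[f].to_numpy())
        kept = bool(np.isfinite(icc) and icc > threshold)
        rows.append({"feature": f, "icc": icc, "kept": kept})
    return RobustnessReport(
        table=pd.DataFrame(rows), n_pairs=len(common), threshold=threshold
    )


def near_zero_variance_filter(
    df: pd.DataFrame,
    freq_ratio: float = 19.0,
    unique_frac: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Drop features with near-zero variance across the cohort.

    A feature is dropped when the ratio of the most-common to second-most
    common value exceeds ``freq_ratio`` AND the number of distinct values is
    below ``unique_frac`` of the rows (the 95/5, 10% convention).  Returns
    (kept, dropped) feature names.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    kept, dropped = [], []
    n = len(df)
    for c in df.columns:
        counts = df[c].value_counts()
        if len(counts) == 1:
            ratio = np.inf
        else:
            ratio = counts.iloc[0] / counts.iloc[1]
        uniq = len(counts) / n
        if ratio > freq_ratio and uniq < unique_frac:
            dropped.append(c)
        else:
            kept.append(c)
    return kept, dropped


@dataclass
class ScalingParams:
    mean: pd.Series
    sd: pd.Series


def center_scale(df: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Center to mean 0 and scale to sample SD 1 (ddof=1) per feature."""
    mean = df.mean()
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero standard deviation for feature(s): {list(zero.index)}"
        )
    return (df - mean) / sd, ScalingParams(mean=mean, sd=sd)


def apply_center_scale(df: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply previously fitted centering/scaling (e.g. to a test fold)."""
    return (df - params.mean[df.columns]) / params.sd[df.columns]
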