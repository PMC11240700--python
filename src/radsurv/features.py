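"""IBSI-aligned feature extraction for a single lesion.

:func:`extract_features` runs the full per-lesion chain: resample ->
discretize -> intensity histogram, shape, GLCM, GLRLM and GLSZM features.
Feature names follow the ``FAMILY_Name`` convention used in the radiomics
literature; the named features carrying IBSI reference codes are listed in
:data:`IBSI_CODES`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    DiscretizationConfig,
    ResamplingSpec,
    discretize_volume,
    resample_volume,
)
from .texture import (
    compute_glcm_features,
    compute_glrlm_features,
    compute_glszm_features,
)

__all__ = [
    "IBSI_CODES",
    "compute_intensity_features",
    "compute_shape_features",
    "extract_features",
    "extract_from_nifti",
]

#: IBSI reference codes for the named result features
IBSI_CODES = {
    "GLSZM_NormalisedZoneSizeNonUniformity": "VB3A",
    "GLSZM_SmallZoneEmphasis": "5QRC",
    "GLSZM_ZonePercentage": "P30P",
    "GLRLM_LongRunsEmphasis": "W4KF",
    "GLRLM_RunPercentage": "9ZK5",
    "GLRLM_ShortRunsEmphasis": "22OV",
}


def compute_intensity_features(
    levels: np.ndarray,
    analysis_mask: np.ndarray,
    hu_values: np.ndarray | None = None,
) -> tuple[dict[str, float], set[str]]:
    """Histogram / intensity statistics on the discretized gray levels.

    Returns (features, undefined) where ``undefined`` names moment features
    that are undefined on the input (single voxel, zero variance); their
    values are reported as 0.  Entropy uses log base 2; energy is the sum of
    squared bin probabilities.
    """
    m = np.asarray(analysis_mask) > 0
    g = np.asarray(levels)[m].astype(float)
    if g.size == 0:
        raise ValueError("empty analysis mask")
    undefined: set[str] = set()

    n_levels = int(g.max())
    counts = np.bincount(g.astype(int), minlength=n_levels + 1)[1:]
    p = counts / g.size
    nz = p > 0

    mean = float(g.mean())
    var = float(g.var())  # population variance (histogram moment)
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((g - mean) ** 3).mean() / sd**3)
        kurt = float(((g - mean) ** 4).mean() / sd**4)
    else:
        skew = kurt = 0.0
        undefined |= {"HIST_Skewness", "HIST_Kurtosis"}

    feats = {
        "HIST_Mean": mean,
        "HIST_Variance": var,
        "HIST_Skewness": skew,
        "HIST_Kurtosis": kurt,
        "HIST_Energy": float((p**2).sum()),
        "HIST_Entropy_log2": float(-(p[nz] * np.log2(p[nz])).sum()),
        "HIST_Min": float(g.min()),
        "HIST_Max": float(g.max()),
        "HIST_Range": float(g.max() - g.min()),
        "HIST_P10": float(np.percentile(g, 10)),
        "HIST_P25": float(np.percentile(g, 25)),
        "HIST_Median": float(np.median(g)),
        "HIST_P75": float(np.percentile(g, 75)),
        "HIST_P90": float(np.percentile(g, 90)),
        "HIST_InterquartileRange": float(
            np.percentile(g, 75) - np.percentile(g, 25)
        ),
    }
    if hu_values is not None:
        hu = np.asarray(hu_values)[m].astype(float)
        feats["HIST_MeanHU"] = float(hu.mean())
        feats["HIST_SdHU"] = float(hu.std(ddof=0))
    return feats, undefined


def compute_shape_features(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> dict[str, float]:
    """Morphological features of the binary mask at the given spacing.

    Surface area uses the voxel-face convention (sum of exposed voxel faces);
    this is stated in the extractor metadata.  Sphericity is
    ``pi^(1/3) (6V)^(2/3) / A``.  The maximum 3-D diameter is the largest
    distance between voxel centers (computed on the convex hull for speed).
    """
    m = np.asarray(mask) > 0
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    vx = np.asarray(voxel_size, dtype=float)
    voxel_vol = float(np.prod(vx))
    volume = n * voxel_vol

    # exposed faces per axis
    area = 0.0
    face_areas = [vx[1] * vx[2], vx[0] * vx[2], vx[0] * vx[1]]
    for ax in range(3):
        padded = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.abs(diff).sum()) * face_areas[ax]

    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    compactness = float(volume / (np.sqrt(np.pi) * area**1.5))

    coords = np.argwhere(m) * vx
    if n == 1:
        max_diam = 0.0
    else:
        pts = coords
        if n > 400:
            try:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(coords)
                pts = coords[hull.vertices]
            except Exception:  # degenerate (coplanar) point sets
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        max_diam = float(np.sqrt(d2.max()))

    centered = coords - coords.mean(axis=0)
    if n > 1:
        ev = np.linalg.eigvalsh(np.cov(centered.T))[::-1]
        ev = np.maximum(ev, 0.0)
        elongation = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
        flatness = float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0

    return {
        "SHAPE_VoxelCount": float(n),
        "SHAPE_Volume_mm3": volume,
        "SHAPE_Volume_cm3": volume / 1000.0,
        "SHAPE_SurfaceArea_mm2": area,
        "SHAPE_SurfaceToVolumeRatio": area / volume,
        "SHAPE_Sphericity": sphericity,
        "SHAPE_Compactness": compactness,
        "SHAPE_MaxDiameter_mm": max_diam,
        "SHAPE_Elongation": elongation,
        "SHAPE_Flatness": flatness,
    }


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    disc: DiscretizationConfig | None = None,
    resampling: ResamplingSpec | None = None,
    resample: bool = True,
) -> dict[str, float]:
    """Full single-lesion feature vector.

    Order of operations: resample (interpolation before discretization), then
    discretize on the HU window, then shape on the resampled mask and
    intensity/texture on the gray-level volume.  Undefined moment features
    are reported as 0 (with a warning); texture features on degenerate
    regions follow the conventions documented in :mod:`radsurv.texture`.
    """
    disc = disc or DiscretizationConfig()
    resampling = resampling or ResamplingSpec()
    if resample:
        volume, mask, spacing = resample_volume(volume, mask, spacing, resampling)
    levels, analysis = discretize_volume(volume, mask, disc)

    feats = compute_shape_features(mask, spacing)
    intens, undefined = compute_intensity_features(levels, analysis, volume)
    if undefined:
        warnings.warn(
            f"undefined moment features reported as 0: {sorted(undefined)}",
            stacklevel=2,
        )
    feats.update(intens)
    n_analysis = int(np.asarray(analysis).sum())
    if n_analysis >= 2:
        feats.update(compute_glcm_features(levels, analysis, disc.n_bins))
        feats.update(compute_glrlm_features(levels, analysis, disc.n_bins))
        feats.update(compute_glszm_features(levels, analysis, disc.n_bins))
    else:
        warnings.warn("texture features skipped: fewer than 2 analysis voxels", stacklevel=2)
    if not all(np.isfinite(v) for v in feats.values()):
        bad = [k for k, v in feats.items() if not np.isfinite(v)]
        raise RuntimeError(f"non-finite feature values: {bad}")
    return feats


def extract_from_nifti(
    volume_path: str | Path,
    mask_path: str | Path,
    disc: DiscretizationConfig | None = None,
    resampling: ResamplingSpec | None = None,
) -> dict[str, float]:
    """Read a NIfTI volume/mask pair and extract the feature vector."""
    import nibabel as nib

    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    return extract_features(
        np.asanyarray(vimg.dataobj).astype(float),
        np.asanyarray(mimg.dataobj) > 0,
        spacing,
        disc=disc,
        resampling=resampling,
    )


def features_to_frame(rows: list[dict], ids: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack per-lesion feature dicts into a lesion-feature table."""
    df = pd.DataFrame(rows)
    if ids is not None:
        df = pd.concat([ids.reset_index(drop=True), df], axis=1)
    return df
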