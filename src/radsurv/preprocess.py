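"""Volume preprocessing: resampling, gray-level discretization, mask erosion.

The extraction pipeline standardizes voxel sizes (b-spline for intensities,
nearest-neighbour for masks), then discretizes Hounsfield units into fixed
2.5-HU bins on the [-100, 200] HU window (120 levels by default); voxels
outside the window are removed from the analysis mask.  Mask erosion (one
voxel, 6-connected) provides the perturbed segmentation used for the
robustness filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizationConfig",
    "ResamplingSpec",
    "UnanalyzableLesionError",
    "resample_volume",
    "discretize_volume",
    "erode_mask",
]


@dataclass
class DiscretizationConfig:
    lower_bound: float = -100.0  # HU
    upper_bound: float = 200.0  # HU
    bin_width: float = 2.5  # HU

    def __post_init__(self) -> None:
        span = self.upper_bound - self.lower_bound
        if span <= 0 or self.bin_width <= 0:
            raise ValueError("bounds must satisfy upper > lower, bin_width > 0")
        n = span / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(upper - lower) / bin_width must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.upper_bound - self.lower_bound) / self.bin_width))


@dataclass
class ResamplingSpec:
    target_voxel: tuple[float, float, float] = (1.0, 1.0, 2.0)  # mm
    intensity_interpolator: str = "b-spline"
    mask_interpolator: str = "nearest"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.target_voxel):
            raise ValueError("target voxel must be strictly positive")


class UnanalyzableLesionError(ValueError):
    """Raised when discretization leaves no analyzable voxel in the mask."""


_SITK_INTERP = {"b-spline": "sitkBSpline", "linear": "sitkLinear", "nearest": "sitkNearestNeighbor"}


def resample_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    spec: ResamplingSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample (volume, mask) from ``spacing`` to ``spec.target_voxel``.

    Arrays are indexed (x, y, z) with ``spacing`` in mm per axis.  Intensities
    are interpolated with the configured interpolator (b-spline by default),
    the mask with nearest neighbour so it stays binary.  Returns the resampled
    pair and the new spacing.
    """
    import SimpleITK as sitk

    if spacing is None:
        raise ValueError("input volume carries no voxel-spacing metadata")
    spec = spec or ResamplingSpec()
    spacing = tuple(float(s) for s in spacing)
    target = tuple(float(t) for t in spec.target_voxel)

    if np.allclose(spacing, target):
        return np.asarray(volume, dtype=float), (np.asarray(mask) > 0).astype(np.uint8), target

    in_size = np.asarray(volume.shape)
    out_size = np.maximum(
        np.round(in_size * np.asarray(spacing) / np.asarray(target)).astype(int), 1
    )

    def _resample(arr: np.ndarray, interp_name: str) -> np.ndarray:
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0)).astype(np.float64)))
        img.SetSpacing(spacing)
        res = sitk.Resample(
            img,
            [int(s) for s in out_size],
            sitk.Transform(),
            getattr(sitk, _SITK_INTERP[interp_name]),
            img.GetOrigin(),
            target,
            img.GetDirection(),
            0.0,
            sitk.sitkFloat64,
        )
        return np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0))

    new_vol = _resample(np.asarray(volume, dtype=float), spec.intensity_interpolator)
    new_mask = _resample((np.asarray(mask) > 0).astype(float), spec.mask_interpolator)
    return new_vol, (new_mask > 0.5).astype(np.uint8), target


def discretize_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    config: DiscretizationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map HU values to integer gray levels 1..B inside the analysis mask.

    Bins are half-open ``[lower + (k-1)w, lower + k*w)`` with the top bin
    closed, so HU == upper_bound maps to level B.  In-mask voxels with HU
    outside [lower, upper] are removed from the analysis mask.  Returns the
    gray-level volume (0 outside the analysis mask) and the analysis mask.
    """
    config = config or DiscretizationConfig()
    vol = np.asarray(volume, dtype=float)
    m = np.asarray(mask) > 0
    analysis = m & (vol >= config.lower_bound) & (vol <= config.upper_bound)
    if m.any() and not analysis.any():
        raise UnanalyzableLesionError(
            "no in-mask voxel falls inside the discretization HU window"
        )
    levels = np.zeros(vol.shape, dtype=np.int32)
    k = np.floor((vol[analysis] - config.lower_bound) / config.bin_width).astype(np.int32) + 1
    levels[analysis] = np.minimum(k, config.n_bins)  # closes the top bin
    return levels, analysis.astype(np.uint8)


#: 6-connected structuring element for the one-voxel erosion
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray) -> np.ndarray:
    """One-voxel 6-connected erosion; may return an empty mask.

    An empty result signals that the lesion is too thin for the
    erosion-robustness comparison and should be excluded from the robustness
    set (the caller decides; this is not fatal).
    """
    m = np.asarray(mask) > 0
    if m.ndim != 3:
        raise ValueError("mask must be 3-D")
    return ndimage.binary_erosion(m, structure=_STRUCT_6, border_value=0).astype(np.uint8)
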