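"""Gray-level texture matrices and derived features.

Three families are implemented on the discretized gray-level volume
(integer levels 1..B inside an analysis mask):

* GLCM — symmetric co-occurrence matrices accumulated at one-voxel
  displacement over the 13 unique 3-D directions; features are averaged over
  directions.
* GLRLM — run-length matrices over the same 13 directions (runs break at mask
  holes and level changes), with directional averaging.
* GLSZM — a single zone-size matrix where zones are 26-connected components
  of equal gray level.

The matrix builders are exposed separately from the feature computations so
that conservation properties (pair/run/zone counts) can be checked against
brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "compute_glcm_features",
    "compute_glrlm_features",
    "compute_glszm_features",
]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                # keep one of each antipodal pair: first nonzero component > 0
                for c in d:
                    if c != 0:
                        if c > 0:
                            dirs.append(d)
                        break
    return tuple(dirs)


#: the 13 unique one-voxel 3-D displacement directions (antipodal pairs merged)
DIRECTIONS_13 = _unique_directions()
assert len(DIRECTIONS_13) == 13


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Return (a, b) gray levels of all in-mask voxel pairs at ``offset``."""
    sl_a, sl_b = [], []
    for o, size in zip(offset, levels.shape):
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(0, size - o))
            sl_b.append(slice(o, size))
        else:
            sl_a.append(slice(-o, size))
            sl_b.append(slice(0, size + o))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = (mask[tuple(sl_a)] > 0) & (mask[tuple(sl_b)] > 0)
    return a[valid], b[valid]


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Symmetric co-occurrence matrix for one direction (unnormalized counts).

    Entry (i, j) counts ordered pairs, accumulated in both directions, so the
    matrix total equals twice the number of unordered pairs.
    """
    a, b = _shifted_pairs(levels, mask, offset)
    m = np.zeros((n_levels, n_levels), dtype=np.int64)
    if a.size:
        np.add.at(m, (a - 1, b - 1), 1)
    return m + m.T


def compute_glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> dict[str, float]:
    """Direction-averaged GLCM features.

    Features (contrast, dissimilarity, homogeneity = inverse difference,
    energy, entropy in bits, correlation) are computed per direction from the
    normalized symmetric matrix and averaged over directions that contain at
    least one voxel pair.  For a constant region the correlation is undefined
    and reported as 1 by convention.
    """
    mask = np.asarray(mask) > 0
    if mask.sum() < 2:
        raise ValueError("GLCM needs at least two analysis voxels")
    idx = np.arange(1, n_levels + 1, dtype=float)
    per_dir: list[dict[str, float]] = []
    for off in directions:
        m = glcm_matrix(levels, mask, off, n_levels)
        tot = m.sum()
        if tot == 0:
            continue
        p = m / tot
        pi = p.sum(axis=1)
        ii = idx[:, None]
        jj = idx[None, :]
        diff = np.abs(ii - jj)
        mu = float((idx * pi).sum())
        sigma2 = float(((idx - mu) ** 2 * pi).sum())
        nz = p > 0
        contrast = float(((ii - jj) ** 2 * p).sum())
        if sigma2 > 0:
            corr = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
        else:
            corr = 1.0
        per_dir.append(
            {
                "Contrast": contrast,
                "Dissimilarity": float((diff * p).sum()),
                "Homogeneity": float((p / (1.0 + diff)).sum()),
                "Energy": float((p**2).sum()),
                "Entropy_log2": float(-(p[nz] * np.log2(p[nz])).sum()),
                "Correlation": corr,
            }
        )
    if not per_dir:
        raise ValueError("no valid voxel pair in any direction")
    return {
        f"GLCM_{k}": float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_along(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Yield (gray level, run length) for maximal runs along ``offset``.

    A run is a maximal sequence of in-mask voxels of equal level spaced by
    ``offset``; out-of-mask voxels (holes) break runs.
    """
    mask = np.asarray(mask) > 0
    shape = levels.shape
    coords = np.argwhere(mask)
    off = np.asarray(offset)

    def inside(c):
        return all(0 <= c[a] < shape[a] for a in range(3))

    in_mask = set(map(tuple, coords))
    for c in coords:
        prev = tuple(c - off)
        ct = tuple(c)
        # start of a run: predecessor absent or different level
        if prev in in_mask and levels[prev] == levels[ct]:
            continue
        length = 1
        nxt = tuple(c + off)
        while nxt in in_mask and levels[nxt] == levels[ct] and inside(nxt):
            length += 1
            nxt = tuple(np.asarray(nxt) + off)
        yield int(levels[ct]), length


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Run-length matrix: entry (i, l-1) counts runs of level i+1, length l."""
    max_len = max(levels.shape)
    m = np.zeros((n_levels, max_len), dtype=np.int64)
    for lev, length in _runs_along(levels, mask, offset):
        if length > m.shape[1]:  # defensive; cannot exceed grid extent
            m = np.pad(m, ((0, 0), (0, length - m.shape[1])))
        m[lev - 1, length - 1] += 1
    return m


def _glrlm_features_from_matrix(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    r_j = m.sum(axis=0).astype(float)
    r_i = m.sum(axis=1).astype(float)
    return {
        "ShortRunsEmphasis": float((r_j / j**2).sum() / n_runs),
        "LongRunsEmphasis": float((r_j * j**2).sum() / n_runs),
        "RunPercentage": float(n_runs / n_voxels),
        "GrayLevelNonUniformity": float((r_i**2).sum() / n_runs),
        "RunLengthNonUniformity": float((r_j**2).sum() / n_runs),
    }


def compute_glrlm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> dict[str, float]:
    """Direction-averaged GLRLM features (RunPercentage = runs / voxels)."""
    mask = np.asarray(mask) > 0
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty analysis mask")
    per_dir = []
    for off in directions:
        m = glrlm_matrix(levels, mask, off, n_levels)
        per_dir.append(_glrlm_features_from_matrix(m, n_vox))
    return {
        f"GLRLM_{k}": float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

#: 26-connectivity structuring element for zone labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size matrix: entry (i, s-1) counts 26-connected zones of level
    i+1 and size s voxels."""
    mask = np.asarray(mask) > 0
    n_vox = int(mask.sum())
    m = np.zeros((n_levels, max(n_vox, 1)), dtype=np.int64)
    present = np.unique(levels[mask])
    for lev in present:
        lab, n_zones = ndimage.label((levels == lev) & mask, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            m[lev - 1, s - 1] += 1
    return m


def compute_glszm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """GLSZM features.

    ZonePercentage = zones / voxels; SmallZoneEmphasis = (1/Nz) * sum_s n_s/s^2;
    NormalisedZoneSizeNonUniformity = sum_s n_s^2 / Nz^2 where n_s is the
    number of zones of size s.
    """
    mask = np.asarray(mask) > 0
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty analysis mask")
    m = glszm_matrix(levels, mask, n_levels)
    n_zones = m.sum()
    s = np.arange(1, m.shape[1] + 1, dtype=float)
    z_s = m.sum(axis=0).astype(float)  # zones per size
    z_i = m.sum(axis=1).astype(float)  # zones per gray level
    return {
        "GLSZM_SmallZoneEmphasis": float((z_s / s**2).sum() / n_zones),
        "GLSZM_LargeZoneEmphasis": float((z_s * s**2).sum() / n_zones),
        "GLSZM_ZonePercentage": float(n_zones / n_vox),
        "GLSZM_ZoneSizeNonUniformity": float((z_s**2).sum() / n_zones),
        "GLSZM_NormalisedZoneSizeNonUniformity": float((z_s**2).sum() / n_zones**2),
        "GLSZM_GrayLevelNonUniformity": float((z_i**2).sum() / n_zones),
    }
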