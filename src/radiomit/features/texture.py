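"""Gray-level run-length, size-zone and neighborhood-tone-difference families.

Conventions (documented constants): GLRLM uses the 13 unique 3D directions
with direction matrices averaged before feature computation; GLSZM uses
26-connectivity; NGTDM uses a box neighborhood whose per-axis half-width
comes from ``offset_to_voxels`` so the physical offset is honored
anisotropically. Conservation identities — sum over a run matrix of
(count x run length), and over a zone matrix of (count x zone size), both
equal the ROI voxel count per direction/matrix — are relied on by tests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_3D",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
]

_EPS = 1e-12

# 13 unique 3D directions: all non-zero {-1,0,1}^3 vectors, keeping one of
# each antipodal pair (first non-zero component positive).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


def _masked_levels(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    lv = np.where(np.asarray(mask, dtype=bool), np.asarray(levels), 0)
    if not (lv > 0).any():
        raise ValueError("no ROI voxels with a positive level")
    return lv.astype(np.int32)


def glrlm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    direction: tuple[int, int, int],
    stride: int = 1,
) -> np.ndarray:
    """Run-length matrix for one direction; rows = gray level (1-based at
    index 0), columns = run length (length 1 at index 0).

    A run is a maximal sequence of in-ROI voxels of equal level along
    ``direction * stride``; out-of-ROI voxels break runs.
    """
    lv = _masked_levels(levels, mask)
    step = np.asarray(direction, dtype=int) * int(stride)
    if not step.any():
        raise ValueError("direction must be non-zero")
    shape = np.asarray(lv.shape)
    n_levels = int(lv.max())

    pos = np.array(np.nonzero(lv)).T  # (m, 3)
    prev = pos - step
    prev_ok = ((prev >= 0) & (prev < shape)).all(axis=1)
    prev_level = np.zeros(len(pos), dtype=np.int32)
    pv = prev[prev_ok]
    prev_level[prev_ok] = lv[pv[:, 0], pv[:, 1], pv[:, 2]]
    here_level = lv[pos[:, 0], pos[:, 1], pos[:, 2]]
    is_start = prev_level != here_level

    starts = pos[is_start]
    run_levels = here_level[is_start]
    run_lengths = np.ones(len(starts), dtype=np.int64)

    cur = starts
    active = np.arange(len(starts))
    while len(active):
        nxt = cur + step
        inside = ((nxt >= 0) & (nxt < shape)).all(axis=1)
        same = np.zeros(len(active), dtype=bool)
        nv = nxt[inside]
        same[inside] = lv[nv[:, 0], nv[:, 1], nv[:, 2]] == run_levels[active][inside]
        run_lengths[active[same]] += 1
        cur = nxt[same]
        active = active[same]

    max_len = int(run_lengths.max())
    mat = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(mat, (run_levels - 1, run_lengths - 1), 1.0)
    return mat


def _glrlm_stats(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    return {
        "glrlm_sre": float((mat / j**2).sum() / n_runs),
        "glrlm_lre": float((mat * j**2).sum() / n_runs),
        "glrlm_gln": float((mat.sum(axis=1) ** 2).sum() / n_runs),
        "glrlm_rln": float((mat.sum(axis=0) ** 2).sum() / n_runs),
        "glrlm_rp": float(n_runs / n_voxels),
        "glrlm_lglre": float((mat / i**2).sum() / n_runs),
        "glrlm_hglre": float((mat * i**2).sum() / n_runs),
    }


def glrlm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
    stride: int = 1,
) -> dict[str, float]:
    """GLRLM features on the direction-averaged run matrix."""
    mats = [glrlm_matrix(levels, mask, d, stride=stride) for d in directions]
    n_lv = max(m.shape[0] for m in mats)
    n_rl = max(m.shape[1] for m in mats)
    avg = np.zeros((n_lv, n_rl))
    for m in mats:
        avg[: m.shape[0], : m.shape[1]] += m
    avg /= len(mats)
    n_voxels = int((_masked_levels(levels, mask) > 0).sum())
    return _glrlm_stats(avg, n_voxels)


def glszm_matrix(
    levels: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Size-zone matrix: rows = gray level, columns = zone size (1-based)."""
    lv = _masked_levels(levels, mask)
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=int)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    n_levels = int(lv.max())
    zones: list[tuple[int, int]] = []
    for level in range(1, n_levels + 1):
        binary = lv == level
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=float)
    for level, size in zones:
        mat[level - 1, size - 1] += 1.0
    return mat


def glszm_features(
    levels: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> dict[str, float]:
    mat = glszm_matrix(levels, mask, connectivity)
    n_zones = mat.sum()
    n_voxels = int((_masked_levels(levels, mask) > 0).sum())
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    return {
        "glszm_sze": float((mat / s**2).sum() / n_zones),
        "glszm_lze": float((mat * s**2).sum() / n_zones),
        "glszm_gln": float((mat.sum(axis=1) ** 2).sum() / n_zones),
        "glszm_zsn": float((mat.sum(axis=0) ** 2).sum() / n_zones),
        "glszm_zp": float(n_zones / n_voxels),
    }


def ngtdm_table(
    levels: np.ndarray,
    mask: np.ndarray,
    distance: tuple[int, int, int] = (1, 1, 1),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occupancy ``p_i`` and tone-difference sums ``s_i``.

    Neighborhood of a voxel: the box of per-axis half-width ``distance``
    centred on it, excluding the centre, intersected with the ROI. Only ROI
    voxels with at least one in-ROI neighbor contribute. Returns
    ``(p, s, n_valid)`` with arrays indexed by level-1.
    """
    lv = _masked_levels(levels, mask)
    m = lv > 0
    dx, dy, dz = (int(d) for d in distance)
    if min(dx, dy, dz) < 1:
        raise ValueError("distance components must be >= 1")
    kernel = np.ones((2 * dx + 1, 2 * dy + 1, 2 * dz + 1))
    kernel[dx, dy, dz] = 0.0

    counts = ndimage.correlate(m.astype(float), kernel, mode="constant", cval=0.0)
    sums = ndimage.correlate(lv.astype(float), kernel, mode="constant", cval=0.0)
    valid = m & (counts > 0.5)
    nbr_mean = np.zeros_like(sums)
    nbr_mean[valid] = sums[valid] / counts[valid]

    n_levels = int(lv.max())
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    vlv = lv[valid]
    diff = np.abs(vlv - nbr_mean[valid])
    np.add.at(p, vlv - 1, 1.0)
    np.add.at(s, vlv - 1, diff)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no ROI voxel has an in-ROI neighbor at this distance")
    p /= n_valid
    return p, s, n_valid


def ngtdm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    distance: tuple[int, int, int] = (1, 1, 1),
) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    p, s, n_valid = ngtdm_table(levels, mask, distance)
    grades = np.arange(1, len(p) + 1, dtype=float)
    nz = p > 0
    n_gp = int(nz.sum())

    coarseness = 1.0 / (float(np.sum(p * s)) + _EPS)

    if n_gp > 1:
        di = grades[:, None] - grades[None, :]
        pp = np.outer(p, p)
        contrast = (
            float((pp * di**2).sum()) / (n_gp * (n_gp - 1)) * float(s.sum()) / n_valid
        )
        ip = grades * p
        busy_den = float(
            np.abs(ip[nz][:, None] - ip[nz][None, :]).sum()
        )
        busyness = float(np.sum(p * s)) / busy_den if busy_den > 0 else 0.0
        pi, si, gi = p[nz], s[nz], grades[nz]
        psum = pi[:, None] + pi[None, :]
        num = np.abs(gi[:, None] - gi[None, :]) * (
            pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        )
        complexity = float((num / psum).sum()) / n_valid
        strength = float((psum * (gi[:, None] - gi[None, :]) ** 2).sum()) / (
            float(s.sum()) + _EPS
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
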