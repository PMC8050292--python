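"""Grey-level matrix families and their features: GLCM (24), GLDM (14),
GLRLM (16), GLSZM (16), NGTDM (5).

Conventions (the extraction-platform defaults the cohort analysis assumes):

* input is a grey-level volume with levels 1..Ng inside the ROI and 0 outside;
* GLCM and GLRLM use the 13 unique 3D direction offsets at distance 1 and the
  per-direction feature values are averaged (not the matrices merged);
* GLCM matrices are symmetrised before normalisation;
* GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity;
* GLDM dependence is counted with tolerance alpha = 0 (equal grey level) and
  the dependence size includes the centre voxel (j = #dependent neighbours+1);
* logarithms are base 2 with a machine-epsilon guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ANGLES_13",
    "GreyLevelMatrix",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_NAMES",
    "GLDM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
]

_EPS = np.spacing(1.0)

# 13 unique direction offsets at Chebyshev distance 1 (one of each +/- pair)
ANGLES_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass
class GreyLevelMatrix:
    """A texture matrix plus the metadata needed to interpret it."""

    family: str
    matrix: np.ndarray  # dense (per family convention), or stacked per angle
    n_grey_levels: int
    angles: tuple | None = None


def _shifted_views(a: np.ndarray, offset: tuple[int, int, int]):
    """Return aligned views (a[v], a[v+offset]) over the overlap region."""
    sl_from, sl_to = [], []
    for d, n in zip(offset, a.shape):
        if d >= 0:
            sl_from.append(slice(0, n - d))
            sl_to.append(slice(d, n))
        else:
            sl_from.append(slice(-d, n))
            sl_to.append(slice(0, n + d))
    return a[tuple(sl_from)], a[tuple(sl_to)]


def _crop_to_bbox(gl: np.ndarray) -> np.ndarray:
    """Crop to the ROI bounding box (texture is translation invariant)."""
    idx = np.argwhere(gl > 0)
    if idx.size == 0:
        raise ValueError("grey-level volume has no ROI voxels")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return gl[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def glcm_matrices(gl_volume: np.ndarray, n_levels: int | None = None) -> GreyLevelMatrix:
    """Symmetrised, normalised co-occurrence matrix per direction.

    Returns a stack of shape (13, Ng, Ng); each slice sums to 1 (directions
    with no admissible pair yield an all-zero slice).
    """
    gl = _crop_to_bbox(np.asarray(gl_volume))
    ng = int(n_levels or gl.max())
    stack = np.zeros((len(ANGLES_13), ng, ng))
    for a, offset in enumerate(ANGLES_13):
        g1, g2 = _shifted_views(gl, offset)
        valid = (g1 > 0) & (g2 > 0)
        if not valid.any():
            continue
        counts = np.zeros((ng, ng))
        np.add.at(counts, (g1[valid] - 1, g2[valid] - 1), 1.0)
        counts = counts + counts.T
        stack[a] = counts / counts.sum()
    return GreyLevelMatrix("GLCM", stack, ng, tuple(ANGLES_13))


def glcm_pair_counts(gl_volume: np.ndarray) -> int:
    """Total number of admissible ordered voxel pairs over the 13 directions
    (after symmetrisation each direction contributes twice its pair count)."""
    gl = _crop_to_bbox(np.asarray(gl_volume))
    total = 0
    for offset in ANGLES_13:
        g1, g2 = _shifted_views(gl, offset)
        total += 2 * int(((g1 > 0) & (g2 > 0)).sum())
    return total


def glrlm_matrices(gl_volume: np.ndarray, n_levels: int | None = None) -> GreyLevelMatrix:
    """Run-length matrix per direction: stack of shape (13, Ng, Lmax).

    A run is a maximal segment of equal grey level along a direction; each
    matrix entry P(i, l) counts runs of level i and length l.
    """
    gl = _crop_to_bbox(np.asarray(gl_volume))
    ng = int(n_levels or gl.max())
    lmax = max(gl.shape)
    mats = np.zeros((len(ANGLES_13), ng, lmax))
    mask = gl > 0
    for a, offset in enumerate(ANGLES_13):
        # forward[v] = length of the same-level run starting at v along +offset
        forward = mask.astype(np.int64)
        same = np.zeros(gl.shape, dtype=bool)
        g1, g2 = _shifted_views(gl, offset)
        s1, _ = _shifted_views(same, offset)
        s1[...] = (g1 > 0) & (g1 == g2)
        while True:
            nxt = forward.copy()
            f1, f2 = _shifted_views(nxt, offset)
            upd = same[tuple(_region_slices(gl.shape, offset))]
            f1[upd] = 1 + f2[upd]
            if np.array_equal(nxt, forward):
                break
            forward = nxt
        # run starts: in-mask voxels whose backward neighbour breaks the run
        start = mask.copy()
        b1, b2 = _shifted_views(gl, tuple(-d for d in offset))
        st1, _ = _shifted_views(start, tuple(-d for d in offset))
        st1[(b1 > 0) & (b1 == b2)] = False
        levels = gl[start] - 1
        lengths = forward[start] - 1
        np.add.at(mats[a], (levels, lengths), 1.0)
    return GreyLevelMatrix("GLRLM", mats, ng, tuple(ANGLES_13))


def _region_slices(shape, offset):
    out = []
    for d, n in zip(offset, shape):
        out.append(slice(0, n - d) if d >= 0 else slice(-d, n))
    return out


def glszm_matrix(gl_volume: np.ndarray, n_levels: int | None = None) -> GreyLevelMatrix:
    """Size-zone matrix: P(i, s) counts 26-connected zones of level i, size s.

    Stored sparsely as an (n_zones, 3) array of (level, size, count) rows
    aggregated over duplicates, to keep LargeArea features exact without a
    dense Ng x Smax allocation.
    """
    gl = _crop_to_bbox(np.asarray(gl_volume))
    ng = int(n_levels or gl.max())
    structure = np.ones((3, 3, 3), dtype=int)
    rows: dict[tuple[int, int], float] = {}
    for level in range(1, ng + 1):
        binary = gl == level
        if not binary.any():
            continue
        labelled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            key = (level, int(s))
            rows[key] = rows.get(key, 0.0) + 1.0
    coo = np.array([(i, s, c) for (i, s), c in sorted(rows.items())], dtype=float)
    return GreyLevelMatrix("GLSZM", coo, ng)


def gldm_matrix(
    gl_volume: np.ndarray, alpha: int = 0, n_levels: int | None = None
) -> GreyLevelMatrix:
    """Dependence matrix: P(i, j) counts voxels of level i whose dependence
    size is j (number of 26-neighbours within ``alpha`` of i, plus one for the
    centre voxel)."""
    gl = _crop_to_bbox(np.asarray(gl_volume))
    ng = int(n_levels or gl.max())
    mask = gl > 0
    dep = np.zeros(gl.shape, dtype=np.int64)
    for offset in _OFFSETS_26:
        g1, g2 = _shifted_views(gl, offset)
        d1, _ = _shifted_views(dep, offset)
        d1 += ((g1 > 0) & (g2 > 0) & (np.abs(g1 - g2) <= alpha)).astype(np.int64)
    jmax = dep[mask].max() + 1
    mat = np.zeros((ng, int(jmax)))
    np.add.at(mat, (gl[mask] - 1, dep[mask]), 1.0)
    return GreyLevelMatrix("GLDM", mat, ng)


def ngtdm_table(gl_volume: np.ndarray, n_levels: int | None = None) -> GreyLevelMatrix:
    """Neighbouring grey-tone difference table.

    Row i holds (n_i, p_i, s_i): the count and fraction of valid voxels with
    level i, and the summed absolute difference between i and the mean level
    of each such voxel's in-ROI 26-neighbourhood.  Voxels without any in-ROI
    neighbour are excluded from the valid set.
    """
    gl = _crop_to_bbox(np.asarray(gl_volume))
    ng = int(n_levels or gl.max())
    mask = gl > 0
    nb_sum = np.zeros(gl.shape, dtype=np.float64)
    nb_cnt = np.zeros(gl.shape, dtype=np.int64)
    for offset in _OFFSETS_26:
        g1, g2 = _shifted_views(gl, offset)
        s1, _ = _shifted_views(nb_sum, offset)
        c1, _ = _shifted_views(nb_cnt, offset)
        inn = g2 > 0
        s1 += np.where(inn, g2, 0)
        c1 += inn.astype(np.int64)
    valid = mask & (nb_cnt > 0)
    nvp = int(valid.sum())
    table = np.zeros((ng, 3))
    if nvp:
        levels = gl[valid]
        diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
        table[:, 0] = np.bincount(levels - 1, minlength=ng)
        np.add.at(table[:, 2], levels - 1, diffs)
        table[:, 1] = table[:, 0] / nvp
    return GreyLevelMatrix("NGTDM", table, ng)


# ---------------------------------------------------------------------------
# family features
# ---------------------------------------------------------------------------

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = np.sqrt(((i - ux) ** 2 * px).sum())
    sy = np.sqrt(((i - uy) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((k_diff * p_diff).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    offdiag = ii != jj
    inv_var = float((p[offdiag] / (ii[offdiag] - jj[offdiag]) ** 2).sum())

    if sx > 0 and sy > 0:
        corr = float(((ii * jj * p).sum() - ux * uy) / (sx * sy))
    else:
        corr = 1.0

    # multivariate correlation coefficient: sqrt of the second largest
    # eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    keep = px > 0
    if keep.sum() > 1:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(0.0, min(eig[-2], 1.0))))
    else:
        mcc = 1.0

    ps_nz = p_sum > 0
    pd_nz = p_diff > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - ux - uy) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[pd_nz] * np.log2(p_diff[pd_nz])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) ** 2) / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[ps_nz] * np.log2(p_sum[ps_nz])).sum()),
        "SumSquares": float(((i - ux) ** 2 * px).sum()),
    }


def glcm_features(glm: GreyLevelMatrix) -> dict[str, float]:
    """Average the 24 co-occurrence features over the 13 directions."""
    per_angle = [_glcm_single(m) for m in glm.matrix if m.sum() > 0]
    if not per_angle:
        raise ValueError("GLCM degenerate: no admissible voxel pair in any direction")
    return {k: float(np.mean([d[k] for d in per_angle])) for k in GLCM_NAMES}


def _weighted_stats(iv, jv, c):
    """Shared emphasis/nonuniformity formula block on (level, size, count)."""
    nz = c.sum()
    p = c / nz
    mu_i = (p * iv).sum()
    mu_j = (p * jv).sum()
    # marginal sums over unique levels / sizes
    gln = sum(c[iv == u].sum() ** 2 for u in np.unique(iv))
    jn = sum(c[jv == u].sum() ** 2 for u in np.unique(jv))
    return {
        "small": float((c / jv**2).sum() / nz),
        "large": float((c * jv**2).sum() / nz),
        "low": float((c / iv**2).sum() / nz),
        "high": float((c * iv**2).sum() / nz),
        "small_low": float((c / (iv**2 * jv**2)).sum() / nz),
        "small_high": float((c * iv**2 / jv**2).sum() / nz),
        "large_low": float((c * jv**2 / iv**2).sum() / nz),
        "large_high": float((c * iv**2 * jv**2).sum() / nz),
        "gln": float(gln / nz),
        "glnn": float(gln / nz**2),
        "jn": float(jn / nz),
        "jnn": float(jn / nz**2),
        "gl_var": float((p * (iv - mu_i) ** 2).sum()),
        "j_var": float((p * (jv - mu_j) ** 2).sum()),
        "entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "nz": float(nz),
    }


GLRLM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def glrlm_features(glm: GreyLevelMatrix, n_voxels: int) -> dict[str, float]:
    """Average the 16 run-length features over the 13 directions."""
    out_per_angle = []
    for mat in glm.matrix:
        if mat.sum() == 0:
            continue
        iv0, jv0 = np.nonzero(mat)
        iv = (iv0 + 1).astype(float)
        jv = (jv0 + 1).astype(float)
        c = mat[iv0, jv0]
        s = _weighted_stats(iv, jv, c)
        out_per_angle.append(
            {
                "ShortRunEmphasis": s["small"],
                "LongRunEmphasis": s["large"],
                "GrayLevelNonUniformity": s["gln"],
                "GrayLevelNonUniformityNormalized": s["glnn"],
                "RunLengthNonUniformity": s["jn"],
                "RunLengthNonUniformityNormalized": s["jnn"],
                "RunPercentage": s["nz"] / n_voxels,
                "GrayLevelVariance": s["gl_var"],
                "RunVariance": s["j_var"],
                "RunEntropy": s["entropy"],
                "LowGrayLevelRunEmphasis": s["low"],
                "HighGrayLevelRunEmphasis": s["high"],
                "ShortRunLowGrayLevelEmphasis": s["small_low"],
                "ShortRunHighGrayLevelEmphasis": s["small_high"],
                "LongRunLowGrayLevelEmphasis": s["large_low"],
                "LongRunHighGrayLevelEmphasis": s["large_high"],
            }
        )
    if not out_per_angle:
        raise ValueError("GLRLM degenerate: no runs found")
    return {k: float(np.mean([d[k] for d in out_per_angle])) for k in GLRLM_NAMES}


GLSZM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]


def glszm_features(glm: GreyLevelMatrix, n_voxels: int) -> dict[str, float]:
    if glm.matrix.size == 0:
        raise ValueError("GLSZM degenerate: no zones")
    iv, jv, c = glm.matrix[:, 0], glm.matrix[:, 1], glm.matrix[:, 2]
    s = _weighted_stats(iv, jv, c)
    return {
        "SmallAreaEmphasis": s["small"],
        "LargeAreaEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "SizeZoneNonUniformity": s["jn"],
        "SizeZoneNonUniformityNormalized": s["jnn"],
        "ZonePercentage": s["nz"] / n_voxels,
        "GrayLevelVariance": s["gl_var"],
        "ZoneVariance": s["j_var"],
        "ZoneEntropy": s["entropy"],
        "LowGrayLevelZoneEmphasis": s["low"],
        "HighGrayLevelZoneEmphasis": s["high"],
        "SmallAreaLowGrayLevelEmphasis": s["small_low"],
        "SmallAreaHighGrayLevelEmphasis": s["small_high"],
        "LargeAreaLowGrayLevelEmphasis": s["large_low"],
        "LargeAreaHighGrayLevelEmphasis": s["large_high"],
    }


GLDM_NAMES = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]


def gldm_features(glm: GreyLevelMatrix) -> dict[str, float]:
    mat = glm.matrix
    iv0, jv0 = np.nonzero(mat)
    iv = (iv0 + 1).astype(float)
    jv = (jv0 + 1).astype(float)  # dependence size includes the centre voxel
    c = mat[iv0, jv0]
    s = _weighted_stats(iv, jv, c)
    return {
        "SmallDependenceEmphasis": s["small"],
        "LargeDependenceEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "DependenceNonUniformity": s["jn"],
        "DependenceNonUniformityNormalized": s["jnn"],
        "GrayLevelVariance": s["gl_var"],
        "DependenceVariance": s["j_var"],
        "DependenceEntropy": s["entropy"],
        "LowGrayLevelEmphasis": s["low"],
        "HighGrayLevelEmphasis": s["high"],
        "SmallDependenceLowGrayLevelEmphasis": s["small_low"],
        "SmallDependenceHighGrayLevelEmphasis": s["small_high"],
        "LargeDependenceLowGrayLevelEmphasis": s["large_low"],
        "LargeDependenceHighGrayLevelEmphasis": s["large_high"],
    }


NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]


def ngtdm_features(glm: GreyLevelMatrix) -> dict[str, float]:
    table = glm.matrix
    n_i = table[:, 0]
    p_i = table[:, 1]
    s_i = table[:, 2]
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("NGTDM degenerate: no voxel with an in-ROI neighbour")
    levels = np.arange(1, glm.n_grey_levels + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    i_p = levels[present]
    p_p = p_i[present]
    s_p = s_i[present]
    s_total = s_i.sum()
    coarse_denom = float((p_i * s_i).sum())

    coarseness = 1.0 / coarse_denom if coarse_denom != 0 else 1e6

    if ngp > 1:
        di = i_p[:, None] - i_p[None, :]
        pp = p_p[:, None] * p_p[None, :]
        contrast = float((pp * di**2).sum() / (ngp * (ngp - 1)) * (s_total / nvp))
        busy_denom = float(np.abs(i_p[:, None] * p_p[:, None] - i_p[None, :] * p_p[None, :]).sum())
        busyness = coarse_denom / busy_denom if busy_denom != 0 else 0.0
        ps = p_p * s_p
        complexity = float(
            (np.abs(di) * (ps[:, None] + ps[None, :]) / (p_p[:, None] + p_p[None, :])).sum() / nvp
        )
        strength = (
            float(((p_p[:, None] + p_p[None, :]) * di**2).sum() / s_total)
            if s_total != 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": strength,
    }
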