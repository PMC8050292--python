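"""Independent straight-from-formula oracle implementations.

Everything here is deliberately written as plain loops over definitions —
rank statistics, ANOVA sums of squares, texture-matrix constructions and the
family feature formulas — so the package's vectorised implementations are
checked against code that shares nothing with them but the definitions.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)

ANGLES = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def ranks_brute(x):
    """Average ranks (1-based, ties averaged) by explicit comparison."""
    x = list(x)
    out = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def spearman_brute(x, y):
    return pearson_brute(ranks_brute(x), ranks_brute(y))


def icc31_brute(m):
    """ICC(3,1) from explicit two-way ANOVA sums of squares."""
    m = [[float(v) for v in row] for row in np.asarray(m)]
    n = len(m)
    k = len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def quantile_brute(xs, q):
    """Linear-interpolation quantile (the classic (n-1)q convention)."""
    s = sorted(xs)
    pos = (len(s) - 1) * q
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def fd_bins_brute(xs):
    xs = list(xs)
    iqr = quantile_brute(xs, 0.75) - quantile_brute(xs, 0.25)
    width = 2.0 * iqr / len(xs) ** (1.0 / 3.0)
    n = (max(xs) - min(xs)) / width
    return max(2, int(math.floor(n + 0.5)))


def sigma_n_brute(xs):
    xs = list(xs)
    n = len(xs)
    mean = sum(xs) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in xs) / (n - 1))
    med = quantile_brute(xs, 0.5)
    return sd / abs(med)


def delta_r_brute(f_thin, f_thick):
    return abs(f_thick - f_thin) / abs(f_thin)


def ccc_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def first_order_brute(raw, gl, voxel_volume):
    raw = [float(v) for v in raw]
    n = len(raw)
    mean = sum(raw) / n
    m2 = sum((v - mean) ** 2 for v in raw) / n
    m3 = sum((v - mean) ** 3 for v in raw) / n
    m4 = sum((v - mean) ** 4 for v in raw) / n
    p10 = quantile_brute(raw, 0.10)
    p90 = quantile_brute(raw, 0.90)
    robust = [v for v in raw if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    counts = {}
    for g in gl:
        counts[g] = counts.get(g, 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in raw)
    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": -sum(p * math.log2(p + EPS) for p in probs),
        "InterquartileRange": quantile_brute(raw, 0.75) - quantile_brute(raw, 0.25),
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": max(raw),
        "Mean": mean,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in raw) / n,
        "Median": quantile_brute(raw, 0.5),
        "Minimum": min(raw),
        "Range": max(raw) - min(raw),
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(sum(v * v for v in raw) / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": sum(p * p for p in probs),
        "Variance": m2,
    }


# ---------------------------------------------------------------------------
# texture matrices by exhaustive enumeration
# ---------------------------------------------------------------------------

def _in(shape, i, j, k):
    return 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]


def glcm_brute_single(gl, offset, ng):
    """Symmetrised normalised co-occurrence matrix by pair enumeration."""
    shape = gl.shape
    counts = np.zeros((ng, ng))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if gl[i, j, k] == 0:
                    continue
                i2, j2, k2 = i + offset[0], j + offset[1], k + offset[2]
                if _in(shape, i2, j2, k2) and gl[i2, j2, k2] > 0:
                    counts[gl[i, j, k] - 1, gl[i2, j2, k2] - 1] += 1
                    counts[gl[i2, j2, k2] - 1, gl[i, j, k] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts, total


def glcm_features_brute(gl, ng):
    feats = []
    for offset in ANGLES:
        p, total = glcm_brute_single(np.asarray(gl), offset, ng)
        if total == 0:
            continue
        feats.append(_glcm_formulas(p, ng))
    keys = feats[0].keys()
    return {k: sum(f[k] for f in feats) / len(feats) for k in keys}


def _glcm_formulas(p, ng):
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i][j]
    hxy = -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j] + EPS)
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    da = sum(k * v for k, v in pdiff.items())
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) > 1:
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in range(ng) if py[k] > 0
                )
        eig = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(0.0, min(eig[-2], 1.0)))
    else:
        mcc = 1.0
    out = {
        "Autocorrelation": sum(
            (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterProminence": sum(
            (i + j + 2 - ux - uy) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - ux - uy) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - ux - uy) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": (
            (
                sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
                - ux * uy
            )
            / (sx * sy)
            if sx > 0 and sy > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in pdiff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
        ),
        "Idn": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "JointAverage": ux,
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in psum.values() if v > 0),
        "SumSquares": sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)),
    }
    return out


def glrlm_brute_single(gl, offset, ng):
    """Run-length matrix by explicit run tracing along one direction."""
    gl = np.asarray(gl)
    shape = gl.shape
    runs = {}
    total = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                level = gl[i, j, k]
                if level == 0:
                    continue
                pi, pj, pk = i - offset[0], j - offset[1], k - offset[2]
                if _in(shape, pi, pj, pk) and gl[pi, pj, pk] == level:
                    continue  # not a run start
                length = 1
                ni, nj, nk = i + offset[0], j + offset[1], k + offset[2]
                while _in(shape, ni, nj, nk) and gl[ni, nj, nk] == level:
                    length += 1
                    ni, nj, nk = ni + offset[0], nj + offset[1], nk + offset[2]
                runs[(level, length)] = runs.get((level, length), 0) + 1
                total += 1
    return runs, total


def _emphasis_formulas(entries, n_voxels):
    """entries: {(level i, size j): count}.  The shared formula block."""
    nz = sum(entries.values())
    levels = sorted({i for i, _ in entries})
    sizes = sorted({j for _, j in entries})
    mu_i = sum(i * c for (i, _), c in entries.items()) / nz
    mu_j = sum(j * c for (_, j), c in entries.items()) / nz
    gln = sum(sum(c for (i, _), c in entries.items() if i == lev) ** 2 for lev in levels)
    jn = sum(sum(c for (_, j), c in entries.items() if j == s) ** 2 for s in sizes)
    ent = -sum((c / nz) * math.log2(c / nz + EPS) for c in entries.values())
    return {
        "small": sum(c / j**2 for (_, j), c in entries.items()) / nz,
        "large": sum(c * j**2 for (_, j), c in entries.items()) / nz,
        "low": sum(c / i**2 for (i, _), c in entries.items()) / nz,
        "high": sum(c * i**2 for (i, _), c in entries.items()) / nz,
        "small_low": sum(c / (i**2 * j**2) for (i, j), c in entries.items()) / nz,
        "small_high": sum(c * i**2 / j**2 for (i, j), c in entries.items()) / nz,
        "large_low": sum(c * j**2 / i**2 for (i, j), c in entries.items()) / nz,
        "large_high": sum(c * i**2 * j**2 for (i, j), c in entries.items()) / nz,
        "gln": gln / nz,
        "glnn": gln / nz**2,
        "jn": jn / nz,
        "jnn": jn / nz**2,
        "gl_var": sum((c / nz) * (i - mu_i) ** 2 for (i, _), c in entries.items()),
        "j_var": sum((c / nz) * (j - mu_j) ** 2 for (_, j), c in entries.items()),
        "entropy": ent,
        "nz": nz,
    }


def glrlm_features_brute(gl, ng, n_voxels):
    feats = []
    for offset in ANGLES:
        runs, total = glrlm_brute_single(gl, offset, ng)
        if total == 0:
            continue
        s = _emphasis_formulas(runs, n_voxels)
        feats.append(
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
    keys = feats[0].keys()
    return {k: sum(f[k] for f in feats) / len(feats) for k in keys}


def glszm_zones_brute(gl, ng):
    """26-connected zones per grey level by breadth-first flood fill."""
    gl = np.asarray(gl)
    shape = gl.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if gl[i, j, k] == 0 or seen[i, j, k]:
                    continue
                level = gl[i, j, k]
                stack = [(i, j, k)]
                seen[i, j, k] = True
                size = 0
                while stack:
                    a, b, c = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBOURS_26:
                        na, nb, nc = a + dx, b + dy, c + dz
                        if (
                            _in(shape, na, nb, nc)
                            and not seen[na, nb, nc]
                            and gl[na, nb, nc] == level
                        ):
                            seen[na, nb, nc] = True
                            stack.append((na, nb, nc))
                zones[(int(level), size)] = zones.get((int(level), size), 0) + 1
    return zones


def glszm_features_brute(gl, ng, n_voxels):
    s = _emphasis_formulas(glszm_zones_brute(gl, ng), n_voxels)
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


def gldm_entries_brute(gl, alpha, ng):
    """Dependence counts per voxel; size includes the centre voxel."""
    gl = np.asarray(gl)
    shape = gl.shape
    entries = {}
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                level = gl[i, j, k]
                if level == 0:
                    continue
                dep = 1
                for dx, dy, dz in NEIGHBOURS_26:
                    ni, nj, nk = i + dx, j + dy, k + dz
                    if (
                        _in(shape, ni, nj, nk)
                        and gl[ni, nj, nk] > 0
                        and abs(int(gl[ni, nj, nk]) - int(level)) <= alpha
                    ):
                        dep += 1
                entries[(int(level), dep)] = entries.get((int(level), dep), 0) + 1
    return entries


def gldm_features_brute(gl, ng, alpha=0):
    s = _emphasis_formulas(gldm_entries_brute(gl, alpha, ng), None)
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


def ngtdm_features_brute(gl, ng):
    gl = np.asarray(gl)
    shape = gl.shape
    n_i = [0] * ng
    s_i = [0.0] * ng
    nvp = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                level = gl[i, j, k]
                if level == 0:
                    continue
                nb = [
                    gl[i + dx, j + dy, k + dz]
                    for dx, dy, dz in NEIGHBOURS_26
                    if _in(shape, i + dx, j + dy, k + dz) and gl[i + dx, j + dy, k + dz] > 0
                ]
                if not nb:
                    continue
                nvp += 1
                n_i[level - 1] += 1
                s_i[level - 1] += abs(level - sum(nb) / len(nb))
    p_i = [c / nvp for c in n_i]
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)
    coarse_denom = sum(p_i[i] * s_i[i] for i in range(ng))
    s_total = sum(s_i)
    if ngp > 1:
        contrast = (
            sum(
                p_i[a] * p_i[b] * (a - b) ** 2
                for a in present
                for b in present
            )
            / (ngp * (ngp - 1))
            * (s_total / nvp)
        )
        busy_den = sum(
            abs((a + 1) * p_i[a] - (b + 1) * p_i[b]) for a in present for b in present
        )
        busyness = coarse_denom / busy_den if busy_den != 0 else 0.0
        complexity = (
            sum(
                abs(a - b)
                * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
                / (p_i[a] + p_i[b])
                for a in present
                for b in present
            )
            / nvp
        )
        strength = (
            sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in present for b in present)
            / s_total
            if s_total != 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": 1.0 / coarse_denom if coarse_denom != 0 else 1e6,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
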