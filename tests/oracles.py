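"""Independent brute-force reference implementations used as test oracles.

Each function here recomputes a statistic or landmark from first principles
(loops, explicit enumeration, closed forms) without going through the package
code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def dice_brute(a: np.ndarray, b: np.ndarray) -> float:
    inter = 0
    na = nb = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        na += bool(va)
        nb += bool(vb)
        inter += bool(va) and bool(vb)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def convex_hull_area_brute(points: np.ndarray) -> float:
    """Monotone-chain convex hull + shoelace area."""
    pts = sorted({(float(x), float(y)) for x, y in points})
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def condylar_slice_brute(mask3d: np.ndarray, spacing, more_distal_tie: bool) -> int:
    """Arg-max slice of convex hull area, explicit loop per slice.

    Areas within 1e-9 (relative) count as tied, matching the tolerance the
    implementation uses for its own tie rule.
    """
    areas = {}
    for k in range(mask3d.shape[2]):
        xs, ys = np.nonzero(mask3d[:, :, k])
        if len(xs) == 0:
            continue
        pts = np.column_stack([(xs + 0.5) * spacing[0], (ys + 0.5) * spacing[1]])
        areas[k] = convex_hull_area_brute(pts)
    best = max(areas.values())
    tol = 1e-9 * max(1.0, best)
    tied = [k for k, a in areas.items() if a >= best - tol]
    return max(tied) if more_distal_tie else min(tied)


def posterior_points_brute(slice2d: np.ndarray, spacing, medial_sign: int):
    """Max-y voxel per medial/lateral half (mean x over the posterior run)."""
    xs, ys = np.nonzero(slice2d)
    xmm = (xs + 0.5) * spacing[0]
    ymm = (ys + 0.5) * spacing[1]
    cx = xmm.mean()
    out = {}
    for name, sign in (("medial", medial_sign), ("lateral", -medial_sign)):
        run_x, best_y = [], None
        for x, y in zip(xmm, ymm):
            if sign * (x - cx) <= 0:
                continue
            if best_y is None or y > best_y:
                best_y, run_x = y, [x]
            elif y == best_y:
                run_x.append(x)
        if best_y is None:
            return None
        out[name] = (float(np.mean(run_x)), float(best_y))
    return out


def icc2_brute(table: np.ndarray):
    """ICC(2,1) from the explicit two-way ANOVA mean squares, with the
    F-bound 95% CI."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # Shrout & Fleiss (1979) case-2 single-score confidence bounds
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + (
        n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f2u = stats.f.ppf(0.975, n - 1, v)
    f2l = stats.f.ppf(0.975, v, n - 1)
    lo = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return icc, (lo, hi)


def mean_abs_diff_brute(x: np.ndarray, y: np.ndarray):
    d = [abs(a - b) for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    var = sum((v - m) ** 2 for v in d) / (n - 1)
    if var == 0:
        return m, (m, m)
    half = stats.t.ppf(0.975, n - 1) * (var ** 0.5) / n ** 0.5
    return m, (m - half, m + half)
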