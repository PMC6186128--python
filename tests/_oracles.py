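"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (pure-Python loops,
Cox-de Boor recursion, numerical integration) so it shares no code path
with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- B-spline MI

def _knots(num_bins: int, order: int) -> list[float]:
    span = num_bins - order + 1
    return [0.0] * order + [float(i) for i in range(1, span)] + [float(span)] * order


def _basis(i: int, k: int, t: list[float], x: float) -> float:
    """Cox-de Boor recursion for the order-k basis function N_{i,k}."""
    if k == 1:
        if t[i] <= x < t[i + 1]:
            return 1.0
        # close the final nonempty interval on the right
        if x == t[-1] and t[i] < t[i + 1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k - 1] != t[i]:
        left = (x - t[i]) / (t[i + k - 1] - t[i]) * _basis(i, k - 1, t, x)
    right = 0.0
    if t[i + k] != t[i + 1]:
        right = (t[i + k] - x) / (t[i + k] - t[i + 1]) * _basis(i + 1, k - 1, t, x)
    return left + right


def bspline_weights(values, num_bins: int, order: int):
    """Per-sample fractional bin memberships, or None for constant input."""
    values = [float(v) for v in values]
    lo, hi = min(values), max(values)
    if hi == lo:
        return None
    span = num_bins - order + 1
    t = _knots(num_bins, order)
    weights = []
    for v in values:
        z = (v - lo) * span / (hi - lo)
        z = min(max(z, 0.0), float(span))
        weights.append([_basis(i, order, t, z) for i in range(num_bins)])
    return weights


def mutual_information(x, y, num_bins: int, order: int) -> float:
    """Plug-in MI (bits) from soft-binned probabilities, all loops."""
    wx = bspline_weights(x, num_bins, order)
    wy = bspline_weights(y, num_bins, order)
    if wx is None or wy is None:
        return 0.0
    n = len(wx)
    px = [sum(w[a] for w in wx) / n for a in range(num_bins)]
    py = [sum(w[b] for w in wy) / n for b in range(num_bins)]
    mi = 0.0
    for a in range(num_bins):
        for b in range(num_bins):
            pab = sum(wx[s][a] * wy[s][b] for s in range(n)) / n
            if pab > 0:
                mi += pab * math.log2(pab / (px[a] * py[b]))
    return max(mi, 0.0)


def histogram_mi(x, y, num_bins: int) -> float:
    """Hard-binned plug-in histogram MI (bits)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    joint, _, _ = np.histogram2d(x, y, bins=num_bins)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(num_bins):
        for b in range(num_bins):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log2(joint[a, b] / (px[a] * py[b]))
    return mi


# ------------------------------------------------------------------------ CLR

def clr_scores(mi) -> np.ndarray:
    """Spreadsheet-style CLR: per-gene background mean/sd (population,
    self excluded), clamped z-scores, Stouffer-style combination."""
    mi = np.asarray(mi, float)
    n = mi.shape[0]
    out = np.zeros_like(mi)
    mu, sd = [], []
    for i in range(n):
        vals = [mi[i, k] for k in range(n) if k != i]
        m = sum(vals) / len(vals)
        v = sum((x - m) ** 2 for x in vals) / len(vals)
        mu.append(m)
        sd.append(math.sqrt(v))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            zi = 0.0 if sd[i] == 0 else max(0.0, (mi[i, j] - mu[i]) / sd[i])
            zj = 0.0 if sd[j] == 0 else max(0.0, (mi[j, i] - mu[j]) / sd[j])
            out[i, j] = math.sqrt(zi**2 + zj**2)
    return out


# ------------------------------------------------------------------ PR / AUPR

def pr_points(scores, labels):
    """Precision/recall at every distinct score cutoff, highest first."""
    pairs = sorted(zip(scores, labels), key=lambda p: -p[0])
    thresholds = sorted({s for s, _ in pairs}, reverse=True)
    pos = sum(labels)
    points = []
    for th in thresholds:
        kept = [lab for s, lab in pairs if s >= th]
        tp = sum(kept)
        points.append((tp / len(kept), tp / pos))
    return points


def aupr(scores, labels) -> float:
    points = pr_points(scores, labels)
    area, prev_recall = 0.0, 0.0
    for precision, recall in points:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# ------------------------------------------------------------------------ MAE

def upper_mae(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += abs(a[i, j] - b[i, j])
            count += 1
    return total / count


# ------------------------------------------------------------------------ FEO

def feo(edges, annotations):
    num = den = 0
    for a, b in edges:
        ca = annotations.get(a, set())
        cb = annotations.get(b, set())
        if ca and cb:
            den += 1
            if ca & cb:
                num += 1
    return None if den == 0 else num / den


# ---------------------------------------------------------------- Welch / CIs

def _t_pdf(u: np.ndarray, df: float) -> np.ndarray:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + u**2 / df) ** (-(df + 1) / 2)


def _simpson(y: np.ndarray, x: np.ndarray) -> float:
    h = x[1] - x[0]
    return float(h / 3 * (y[0] + y[-1] + 4 * y[1:-1:2].sum() + 2 * y[2:-1:2].sum()))


def t_sf(t: float, df: float) -> float:
    """P(T > t), t >= 0, via Simpson integration of the density over
    [0, t] and symmetry (avoids truncating an infinite tail)."""
    u = np.linspace(0.0, abs(t), 20_001)
    return 0.5 - _simpson(_t_pdf(u, df), u)


def t_quantile(p: float, df: float) -> float:
    """Upper quantile (p > 0.5) by bisection on the integrated density."""
    lo, hi = 0.0, 1000.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if 1.0 - t_sf(mid, df) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def welch(xs, ys):
    """Welch statistic, Welch-Satterthwaite df and two-sided p."""
    xs = [float(v) for v in xs]
    ys = [float(v) for v in ys]
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((v - mx) ** 2 for v in xs) / (nx - 1)
    vy = sum((v - my) ** 2 for v in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * t_sf(abs(t), df)
    return t, df, min(p, 1.0)
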