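"""Independent oracles used by the test suite.

Everything here is deliberately naive — loop-based formulas, dense
sampling, generic numeric optimization — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def similarity_objective(params, src, dst):
    """Sum of squared residuals for p -> s R(theta) p + t."""
    s, theta, tx, ty = params
    c, sn = math.cos(theta), math.sin(theta)
    x = s * (c * src[:, 0] - sn * src[:, 1]) + tx - dst[:, 0]
    y = s * (sn * src[:, 0] + c * src[:, 1]) + ty - dst[:, 1]
    return float(np.sum(x * x + y * y))


def brute_force_similarity(src, dst):
    """Best similarity parameters by generic numeric minimization.

    Multi-start Nelder-Mead from rough data-driven initializations; returns
    the smallest objective value found."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    spread_src = np.linalg.norm(src - src.mean(axis=0))
    spread_dst = np.linalg.norm(dst - dst.mean(axis=0))
    s0 = spread_dst / spread_src if spread_src > 0 else 1.0
    t0 = dst.mean(axis=0) - src.mean(axis=0)
    best = np.inf
    rng = np.random.default_rng(12345)
    starts = [(s0, th, *t0) for th in np.linspace(-np.pi, np.pi, 9, endpoint=False)]
    starts += [
        (s0 * rng.uniform(0.5, 2.0), rng.uniform(-np.pi, np.pi),
         t0[0] + rng.normal(0, 5), t0[1] + rng.normal(0, 5))
        for _ in range(6)
    ]
    for x0 in starts:
        res = minimize(
            similarity_objective, x0, args=(src, dst), method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 20000, "maxfev": 20000},
        )
        best = min(best, res.fun)
    return best


def even_odd_inside(point, rings):
    """Even-odd (ray-crossing) point-in-filled-region test.

    ``rings`` is a list of (n, 2) closed or open coordinate arrays (outer
    and hole rings alike); crossings are counted over all of them, so a
    point inside a hole counts as outside."""
    x, y = point
    crossings = 0
    for ring in rings:
        ring = np.asarray(ring, float)
        n = len(ring)
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                if x_cross > x:
                    crossings += 1
    return crossings % 2 == 1


def dense_boundary_distance(point, rings, n_samples=100_000):
    """Unsigned distance via dense arc-length sampling of the boundary.

    Accurate to ~spacing^2 / (8 d) for a query at distance d, so queries
    closer than about a tenth of the sample spacing should not be checked
    against it at tight tolerances."""
    point = np.asarray(point, float)
    total_len = 0.0
    prepared = []
    for ring in rings:
        ring = np.asarray(ring, float)
        if not np.allclose(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[0]])
        seg = np.diff(ring, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        prepared.append((ring, cum))
        total_len += cum[-1]
    best = np.inf
    for ring, cum in prepared:
        n = max(16, int(round(n_samples * cum[-1] / total_len)))
        t = np.linspace(0.0, cum[-1], n, endpoint=False)
        xs = np.interp(t, cum, ring[:, 0])
        ys = np.interp(t, cum, ring[:, 1])
        best = min(best, float(np.min(np.hypot(xs - point[0], ys - point[1]))))
    return best


def anova_icc_a1(x):
    """ICC(A,1) from explicitly looped two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(x[i]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(x[:, j]) / n - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def srd_from_formula_chain(x):
    """Smallest real difference evaluated step by step: pooled SD of all
    measurements, SEM = SD sqrt(1 - ICC(A,1)), SRD = 1.96 sqrt(2) SEM."""
    x = np.asarray(x, float)
    icc = anova_icc_a1(x)
    flat = x.reshape(-1)
    mean = flat.mean()
    sd = math.sqrt(sum((v - mean) ** 2 for v in flat) / (len(flat) - 1))
    sem = sd * math.sqrt(1 - icc)
    return 1.96 * math.sqrt(2) * sem
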