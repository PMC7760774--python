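"""Independent brute-force oracles used by the test suite."""
import numpy as np


def naive_vslope(binned, min_segment=3, min_slope_gap=0.10):
    """Exhaustive reimplementation of the v-slope detector.

    Mirrors the shipped algorithm step by step with plain numpy: VCO2
    smoothing by an explicit 3-point window, VO2 axis replaced by its
    linear-in-time trend when R^2 >= 0.95, then a scan of every hinge
    joint with a least-squares fit at each candidate.
    """
    x = binned["vo2"].to_numpy(float)
    t = binned["t_end"].to_numpy(float)
    y = binned["vco2"].to_numpy(float)

    # VO2 axis conditioning
    var_x = ((x - x.mean()) ** 2).sum()
    if var_x > 0:
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        rss = ((x - A @ coef) ** 2).sum()
        if coef[1] > 0 and 1.0 - rss / var_x >= 0.95:
            x = A @ coef

    # VCO2 smoothing
    if y.size >= 3:
        ys = np.empty_like(y)
        for i in range(y.size):
            lo = max(0, i - 1)
            hi = min(y.size, i + 2)
            ys[i] = y[lo:hi].mean()
        ys[0] = y[0]
        ys[-1] = y[-1]
        y = ys

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    candidates = []
    for k in range(min_segment, x.size - min_segment + 1):
        xk = 0.5 * (x[k - 1] + x[k])
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xk)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if coef[2] < min_slope_gap:
            continue
        rss = float(((y - X @ coef) ** 2).sum())
        candidates.append((rss, xk))
    return min(candidates)[1] if candidates else None
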