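"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def ssim_sliding_window(x, y, data_range, sigma=1.5, truncate=3.5,
                        k1=0.01, k2=0.03):
    """SSIM by explicit Gaussian-weighted window statistics (interior only)."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    k = np.exp(-ax ** 2 / (2 * sigma ** 2))
    k /= k.sum()
    w = np.outer(k, k)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    vals = []
    for i in range(radius, x.shape[0] - radius):
        for j in range(radius, x.shape[1] - radius):
            wx = x[i - radius:i + radius + 1, j - radius:j + radius + 1]
            wy = y[i - radius:i + radius + 1, j - radius:j + radius + 1]
            ux, uy = (w * wx).sum(), (w * wy).sum()
            vx = (w * wx * wx).sum() - ux * ux
            vy = (w * wy * wy).sum() - uy * uy
            cov = (w * wx * wy).sum() - ux * uy
            vals.append(((2 * ux * uy + c1) * (2 * cov + c2))
                        / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def spearman_no_ties(x, y):
    """rho = 1 - 6 sum d^2 / (n (n^2 - 1)); valid when neither input has ties."""
    def ranks(v):
        r = np.empty(len(v))
        r[np.argsort(v)] = np.arange(1, len(v) + 1)
        return r
    d = ranks(np.asarray(x)) - ranks(np.asarray(y))
    n = len(d)
    return 1.0 - 6.0 * float((d ** 2).sum()) / (n * (n ** 2 - 1))


def weighted_kappa_from_table(table, weights="linear"):
    """kappa = 1 - sum(w*O)/sum(w*E) from a square contingency table."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    o = table / table.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    if weights == "quadratic":
        w = w ** 2
    return 1.0 - float((w * o).sum()) / float((w * e).sum())


def bland_altman_by_hand(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    bias = d.sum() / n
    sd = np.sqrt(((d - bias) ** 2).sum() / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
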