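"""Independent brute-force reference implementations used only by tests.

Each function re-derives a metric from its textbook definition with explicit
loops/sums, deliberately avoiding the code paths (and where possible the
libraries) used by the package implementation.
"""

import numpy as np


def nrmse_direct(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.sqrt(((x - y) ** 2).sum() / x.size) / (y.sum() / y.size))


def pearson_direct(x, y):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    sx, sy = x.sum(), y.sum()
    cov = (x * y).sum() - sx * sy / n
    vx = (x * x).sum() - sx * sx / n
    vy = (y * y).sum() - sy * sy / n
    return float(cov / np.sqrt(vx * vy))


def dct2_cosine_sum(img):
    """Orthonormal 2D DCT-II evaluated by the explicit double cosine sum."""
    img = np.asarray(img, float)
    n1, n2 = img.shape
    out = np.zeros_like(img)
    for k1 in range(n1):
        s1 = np.sqrt(1.0 / n1) if k1 == 0 else np.sqrt(2.0 / n1)
        for k2 in range(n2):
            s2 = np.sqrt(1.0 / n2) if k2 == 0 else np.sqrt(2.0 / n2)
            acc = 0.0
            for m in range(n1):
                c1 = np.cos(np.pi * (2 * m + 1) * k1 / (2 * n1))
                for n in range(n2):
                    acc += img[m, n] * c1 * np.cos(
                        np.pi * (2 * n + 1) * k2 / (2 * n2))
            out[k1, k2] = s1 * s2 * acc
    return out


def iic_cosine_sum(img):
    """Spectral Shannon entropy via the explicit-cosine-sum DCT."""
    coeffs = dct2_cosine_sum(img)
    f = coeffs ** 2 / float(img.size) ** 2
    total = f.sum()
    if total == 0:
        return 0.0
    p = (f / total).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _gaussian_kernel_1d(sigma, radius):
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * x ** 2 / sigma ** 2)
    return k / k.sum()


def ssim_windowed(x, y, sigma=1.5, k1=0.01, k2=0.03, data_range=None):
    """2D SSIM with Gaussian-weighted windows by explicit per-pixel loops.

    Window radius, padding behaviour (symmetric reflection) and border crop
    follow the standard Gaussian-weighted formulation with truncation at
    3.5 sigma; population (weighted) covariances are used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if data_range is None:
        data_range = y.max() - y.min()
    radius = int(3.5 * sigma + 0.5)
    g1 = _gaussian_kernel_1d(sigma, radius)
    w = np.outer(g1, g1)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    xp = np.pad(x, radius, mode="symmetric")
    yp = np.pad(y, radius, mode="symmetric")
    h, wid = x.shape
    s = np.zeros_like(x)
    for i in range(h):
        for j in range(wid):
            wx = xp[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            wy = yp[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            ux = (w * wx).sum()
            uy = (w * wy).sum()
            vx = (w * wx * wx).sum() - ux ** 2
            vy = (w * wy * wy).sum() - uy ** 2
            cxy = (w * wx * wy).sum() - ux * uy
            s[i, j] = (((2 * ux * uy + c1) * (2 * cxy + c2))
                       / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    crop = radius
    return float(s[crop:h - crop, crop:wid - crop].mean())
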