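"""Independent scalar-loop oracles for metrics and loss primitives.

Everything here is written with explicit Python loops and two-pass moment
formulas, deliberately sharing no code with the package implementations it
cross-checks.
"""

import math

import numpy as np


# metric oracles -------------------------------------------------------
def entropy(x):
    counts = [0] * 256
    for row in x:
        for v in row:
            counts[min(int(v * 256), 255)] += 1
    total = float(sum(counts))
    en = 0.0
    for c in counts:
        if c:
            p = c / total
            en -= p * math.log2(p)
    return en


def std_dev(x):
    m, n = len(x), len(x[0])
    mu = sum(v for row in x for v in row) / (m * n)
    ss = sum((v - mu) ** 2 for row in x for v in row)
    return math.sqrt(ss / (m * n))


def mean_gradient(x):
    m, n = len(x), len(x[0])
    total = 0.0
    for i in range(1, m):
        for j in range(1, n):
            dv = x[i][j] - x[i - 1][j]
            dh = x[i][j] - x[i][j - 1]
            total += math.sqrt((dv * dv + dh * dh) / 2.0)
    return total / ((m - 1) * (n - 1))


def spatial_frequency(x):
    m, n = len(x), len(x[0])
    rf = sum((x[i][j] - x[i][j - 1]) ** 2 for i in range(m) for j in range(1, n))
    cf = sum((x[i][j] - x[i - 1][j]) ** 2 for i in range(1, m) for j in range(n))
    return math.sqrt(rf / (m * n) + cf / (m * n))


def psnr(a, b):
    m, n = len(a), len(a[0])
    mse = sum((a[i][j] - b[i][j]) ** 2 for i in range(m) for j in range(n)) / (m * n)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def _moments(w):
    m, n = len(w), len(w[0])
    mu = sum(v for row in w for v in row) / (m * n)
    var = sum((v - mu) ** 2 for row in w for v in row) / (m * n)
    return mu, var


def q0(a, f):
    mu_a, va = _moments(a)
    mu_f, vf = _moments(f)
    m, n = len(a), len(a[0])
    cov = sum((a[i][j] - mu_a) * (f[i][j] - mu_f) for i in range(m) for j in range(n)) / (m * n)
    den = (va + vf) * (mu_a**2 + mu_f**2)
    if va == 0.0 and vf == 0.0:
        return 1.0 if (mu_a == mu_f and mu_a != 0.0) else 0.0
    if den == 0.0:
        return 0.0
    return 4.0 * cov * mu_a * mu_f / den


def qabf(a, b, f, window=8):
    a, b, f = np.asarray(a), np.asarray(b), np.asarray(f)
    m, n = a.shape
    vals = []
    for i in range(m - window + 1):
        for j in range(n - window + 1):
            wa = a[i : i + window, j : j + window]
            wb = b[i : i + window, j : j + window]
            wf = f[i : i + window, j : j + window]
            _, va = _moments(wa)
            _, vb = _moments(wb)
            lam = va / (va + vb) if va + vb > 0.0 else 0.5
            vals.append(lam * q0(wa, wf) + (1.0 - lam) * q0(wb, wf))
    return sum(vals) / len(vals)


# loss oracles ---------------------------------------------------------
def gaussian_kernel(size=11, sigma=1.5):
    k = [[0.0] * size for _ in range(size)]
    c = (size - 1) / 2.0
    total = 0.0
    for i in range(size):
        for j in range(size):
            k[i][j] = math.exp(-((i - c) ** 2 + (j - c) ** 2) / (2.0 * sigma**2))
            total += k[i][j]
    return [[v / total for v in row] for row in k]


def ssim(x, y, size=11, sigma=1.5, c1=1e-4, c2=9e-4):
    x, y = np.asarray(x), np.asarray(y)
    k = gaussian_kernel(size, sigma)
    m, n = x.shape
    vals = []
    for i in range(m - size + 1):
        for j in range(n - size + 1):
            mx = my = 0.0
            for a in range(size):
                for b in range(size):
                    mx += k[a][b] * x[i + a][j + b]
                    my += k[a][b] * y[i + a][j + b]
            vx = vy = cxy = 0.0
            for a in range(size):
                for b in range(size):
                    vx += k[a][b] * x[i + a][j + b] ** 2
                    vy += k[a][b] * y[i + a][j + b] ** 2
                    cxy += k[a][b] * x[i + a][j + b] * y[i + a][j + b]
            vx -= mx * mx
            vy -= my * my
            cxy -= mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * cxy + c2))
                / ((mx * mx + my * my + c1) * (vx + vy + c2))
            )
    return sum(vals) / len(vals)


def tv_norm(x):
    m, n = len(x), len(x[0])
    total = 0.0
    for i in range(m):
        for j in range(1, n):
            total += abs(x[i][j] - x[i][j - 1])
    for i in range(1, m):
        for j in range(n):
            total += abs(x[i][j] - x[i - 1][j])
    return total / (m * n)


def frob_dist(x, y):
    m, n = len(x), len(x[0])
    ss = sum((x[i][j] - y[i][j]) ** 2 for i in range(m) for j in range(n))
    return math.sqrt(ss) / math.sqrt(m * n)
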