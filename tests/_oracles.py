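"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's computational paths: the CWT oracle
is an O(N^2) direct circular convolution with the time-sampled periodized
Morlet daughter; the statistics oracles are textbook formulas evaluated
directly.
"""

import numpy as np


def direct_cwt(x: np.ndarray, scales, omega0: float = 6.0, dt: float = 1.0,
               nfft: int | None = None) -> np.ndarray:
    """Morlet CWT by explicit time-domain circular convolution.

    The series is mean-removed and zero-padded to ``nfft`` (next power of two
    above n by default); each daughter is sampled in the time domain,
    periodized over the padded circle, and convolved by direct summation.
    """
    x = np.asarray(x, float)
    n = x.size
    if nfft is None:
        nfft = int(2 ** (int(np.floor(np.log2(n))) + 1))
    xd = x - x.mean()
    xp = np.concatenate([xd, np.zeros(nfft - n)])
    scales = np.atleast_1d(np.asarray(scales, float))
    out = np.empty((scales.size, n), dtype=complex)
    m = np.arange(nfft)
    for si, s in enumerate(scales):
        gper = np.zeros(nfft, dtype=complex)
        for j in range(-4, 5):  # periodize the daughter over the circle
            tt = (m + j * nfft) * dt / s
            gper += np.sqrt(dt / s) * np.pi**-0.25 * np.exp(1j * omega0 * tt - tt**2 / 2.0)
        for t0 in range(n):
            out[si, t0] = np.sum(xp * np.conj(gper[(m - t0) % nfft]))
    return out


def rm_anova_f(values: np.ndarray) -> tuple[float, int, int]:
    """Brute-force one-way repeated-measures F via explicit deviation sums."""
    y = np.asarray(values, float)
    n, k = y.shape
    grand = y.mean()
    ss_band = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (y[i, j] - y[i, :].mean() - y[:, j].mean() + grand) ** 2
    df1, df2 = k - 1, (n - 1) * (k - 1)
    return (ss_band / df1) / (ss_err / df2), df1, df2


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook paired t statistic and two-sided p."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2.0 * tdist.sf(abs(t), n - 1)


def ar1_sim(rng, phi: float, n: int) -> np.ndarray:
    """Plain-loop stationary AR(1) with unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.standard_normal() * np.sqrt(1 - phi**2)
    return x
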