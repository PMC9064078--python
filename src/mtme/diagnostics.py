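"""Chain diagnostics: Geweke z, HPD intervals, posterior mode, ESS.

All functions are pure: they take a 1-D array of retained samples of a
single scalar parameter and return a number (or interval).  The Geweke
statistic compares the means of an early and a late chain window, with
window variances taken from the spectral density at frequency zero
estimated by an autoregressive fit whose order is chosen by AIC.  HPD
intervals use the Chen–Shao empirical method (narrowest window of
consecutive order statistics).  Effective sample size uses Geyer's
initial-positive-sequence truncation of the autocorrelation sum.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.stats import gaussian_kde

__all__ = [
    "DegenerateChainError",
    "geweke_z",
    "hpd_interval",
    "posterior_mode",
    "effective_size",
    "spectral_density_at_zero",
]


class DegenerateChainError(ValueError):
    """The chain has (numerically) zero variance; the diagnostic is undefined."""


def _as_chain(x, min_len: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_len:
        raise ValueError(f"chain too short ({arr.size} < {min_len})")
    if not np.all(np.isfinite(arr)):
        raise ValueError("chain contains non-finite values")
    return arr


def spectral_density_at_zero(x: np.ndarray, max_order: int | None = None) -> float:
    """Estimate S(0), the spectral density of the chain at frequency zero.

    Fits AR(p) models by Yule-Walker for p = 0..max_order, picks the
    order minimizing AIC, and returns
    sigma^2 / (1 - sum(phi))^2  (the AR spectral density at omega=0).
    """
    x = _as_chain(x, 4)
    n = x.size
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var <= 0 or not np.isfinite(var):
        raise DegenerateChainError("zero-variance window")
    if max_order is None:
        max_order = int(min(10 * np.log10(n), n // 4))
    # autocovariances
    nlags = max_order
    acov = np.array([float(xc[: n - k] @ xc[k:]) / n for k in range(nlags + 1)])
    best_aic = np.inf
    best_s0 = var  # p = 0: white noise
    aic0 = n * np.log(var) + 2 * 0
    best_aic = aic0
    for p in range(1, max_order + 1):
        # Yule-Walker: Toeplitz(acov[0..p-1]) phi = acov[1..p]
        try:
            phi = solve_toeplitz(acov[:p], acov[1 : p + 1])
        except np.linalg.LinAlgError:
            break
        sigma2 = acov[0] - phi @ acov[1 : p + 1]
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2 * p
        if aic < best_aic:
            best_aic = aic
            denom = 1.0 - phi.sum()
            if abs(denom) < 1e-10:
                continue
            best_s0 = sigma2 / denom**2
    return float(best_s0)


def geweke_z(chain, frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence z-score.

    Compares the mean of the first ``frac_first`` of the chain with the
    mean of the last ``frac_last``, scaled by spectral-density variance
    estimates; approximately N(0, 1) for a converged chain.
    """
    x = _as_chain(chain)
    if frac_first <= 0 or frac_last <= 0 or frac_first + frac_last > 1:
        raise ValueError("require frac_first, frac_last > 0 and their sum <= 1")
    n = x.size
    n1 = int(np.floor(frac_first * n))
    n2 = int(np.floor(frac_last * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("windows must contain at least 10 samples")
    first, last = x[:n1], x[n - n2 :]
    s1 = spectral_density_at_zero(first)
    s2 = spectral_density_at_zero(last)
    denom = np.sqrt(s1 / n1 + s2 / n2)
    if denom == 0:
        raise DegenerateChainError("zero spectral variance in both windows")
    return float((first.mean() - last.mean()) / denom)


def hpd_interval(chain, prob: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval, Chen–Shao empirical method.

    Sorts the samples and returns the narrowest window containing
    ceil(prob * n) consecutive order statistics; ties go to the lowest
    start index.  Both endpoints are observed sample values.
    """
    x = _as_chain(chain, 1)
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    n = x.size
    if n * (1 - prob) < 1:
        raise ValueError(
            f"interval undefined: n*(1-prob) = {n * (1 - prob):.3g} < 1"
        )
    xs = np.sort(x)
    m = int(np.ceil(prob * n))
    widths = xs[m - 1 :] - xs[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(xs[i]), float(xs[i + m - 1])


def posterior_mode(chain, gridsize: int = 512) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a fixed
    512-point grid spanning the sample range; deterministic given the chain."""
    x = _as_chain(chain, 1)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0 or np.std(x) == 0:
        return lo
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, gridsize)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def effective_size(chain) -> float:
    """Effective sample size n / (1 + 2 sum_k rho_k), autocorrelations
    truncated by Geyer's initial positive sequence."""
    x = _as_chain(chain, 4)
    n = x.size
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var <= 0:
        raise DegenerateChainError("degenerate chain: zero variance")
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real
    acf /= acf[0]
    # Geyer initial positive sequence on paired sums
    tau = -1.0
    k = 0
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        k += 2
    tau = max(tau, 1.0 / n)
    ess = n / tau
    return float(min(ess, n * (1.0 + 1e-9)))
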