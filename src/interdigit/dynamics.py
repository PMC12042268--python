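"""Time-series statistics for per-frame interdigitation metrics.

Autocorrelation of the per-frame nISA / contact-total series decays on
two timescales (fast local chain motion, slow collective relaxation),
captured by a constrained double-exponential fit

    ACF(t) ~ A exp(-t/tau_slow) + (1 - A) exp(-t/tau_fast).

Standard errors of trajectory means are estimated by block averaging:
block sizes double until the blocked standard error plateaus, which
corrects the naive sqrt(n) error for serial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class ACF:
    """Normalized autocorrelation function of a uniformly sampled series."""

    lags: np.ndarray       # time units of dt
    values: np.ndarray     # dimensionless, values[0] == 1
    dt: float = 1.0        # ns per sample


@dataclass
class DoubleExpFit:
    """Double-exponential ACF fit with amplitudes constrained to sum to 1."""

    a_slow: float
    tau_slow: float
    a_fast: float
    tau_fast: float
    residual: float          # L2 norm of fit residuals
    degenerate: bool = False  # tau_slow ~ tau_fast: effectively single-exp

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (self.a_slow * np.exp(-t / self.tau_slow)
                + self.a_fast * np.exp(-t / self.tau_fast))


@dataclass
class BlockAverageResult:
    se: float                 # standard error of the series mean
    block_size: int           # block length at the plateau (samples)
    plateau_found: bool
    block_sizes: np.ndarray
    block_ses: np.ndarray


def autocorrelation(values, dt: float = 1.0, max_lag: int | None = None,
                    method: str = "direct") -> ACF:
    """Normalized autocovariance of a uniformly sampled series.

    ``method="direct"`` uses the unbiased estimator (sum over the n-k
    available pairs at lag k, divided by n-k); ``method="fft"`` computes
    the same numerator via FFT convolution and applies the identical
    normalization, for long series.  ACF(0) = 1 by construction.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("at least 10 samples are required")
    var = np.var(x)
    if var == 0:
        raise ValueError("constant series has undefined autocorrelation")
    if max_lag is None:
        max_lag = n // 5
    max_lag = min(max_lag, n - 1)
    d = x - x.mean()
    if method == "direct":
        acf = np.empty(max_lag + 1)
        for k in range(max_lag + 1):
            acf[k] = np.mean(d[: n - k] * d[k:])
    elif method == "fft":
        m = 1 << (2 * n - 1).bit_length()
        f = np.fft.rfft(d, m)
        full = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1]
        acf = full / (n - np.arange(max_lag + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    acf = acf / acf[0]
    return ACF(lags=np.arange(max_lag + 1) * dt, values=acf, dt=dt)


def _fit_window(acf: ACF, noise_floor: float):
    """Lags up to the first dip of the ACF below the noise floor."""
    below = np.flatnonzero(acf.values < noise_floor)
    stop = below[0] if below.size else len(acf.values)
    return acf.lags[:stop], acf.values[:stop]


def fit_double_exponential(acf: ACF, noise_floor: float = 0.01,
                           constrain_sum: bool = True) -> DoubleExpFit:
    """Fit A1 exp(-t/tau1) + A2 exp(-t/tau2) to an ACF.

    With ``constrain_sum`` (default) the amplitudes satisfy A1 + A2 = 1,
    matching ACF(0) = 1.  The fit window runs to the first lag where the
    ACF drops below ``noise_floor``.  Multiple starting points are tried
    and the best least-squares solution returned; if the two timescales
    collapse onto each other the result is flagged ``degenerate`` and is
    effectively a single exponential.
    """
    t, y = _fit_window(acf, noise_floor)
    if len(t) < 10:
        raise ValueError("fewer than 10 ACF lags above the noise floor")
    t_span = max(t[-1], acf.dt)

    if constrain_sum:
        def model(tt, a, tau1, tau2):
            return a * np.exp(-tt / tau1) + (1 - a) * np.exp(-tt / tau2)
        bounds = ([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf])
        starts = [(0.5, t_span, t_span / 10),
                  (0.3, t_span / 2, t_span / 50),
                  (0.7, 2 * t_span, t_span / 5),
                  (0.5, t_span / 5, t_span / 100)]
    else:
        def model(tt, a, tau1, tau2, a2):
            return a * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)
        bounds = ([0.0, 1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf, np.inf])
        starts = [(0.5, t_span, t_span / 10, 0.5),
                  (0.3, t_span / 2, t_span / 50, 0.7)]

    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                         maxfev=20000, xtol=1e-14, ftol=1e-14)
        except RuntimeError:
            continue
        res = float(np.linalg.norm(y - model(t, *popt)))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError("double-exponential fit did not converge; "
                           "inspect the ACF window and noise floor")
    popt, res = best
    if constrain_sum:
        a1, tau1, tau2 = popt
        a2 = 1.0 - a1
    else:
        a1, tau1, tau2, a2 = popt
    if tau1 < tau2:
        a1, a2 = a2, a1
        tau1, tau2 = tau2, tau1
    degenerate = abs(tau1 - tau2) <= 1e-3 * tau1
    return DoubleExpFit(a_slow=float(a1), tau_slow=float(tau1),
                        a_fast=float(a2), tau_fast=float(tau2),
                        residual=res, degenerate=degenerate)


def block_average_error(values, plateau_rtol: float = 0.05
                        ) -> BlockAverageResult:
    """Standard error of a correlated series' mean by block averaging.

    The series is cut into contiguous blocks whose size doubles
    (1, 2, 4, ...); at each size the SE of the block means is computed.
    The reported SE is taken at the plateau, detected as a change below
    ``plateau_rtol`` across two successive doublings; if no plateau is
    reached the largest usable block size is used and flagged.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 32:
        raise ValueError("at least 32 samples are required for block averaging")
    if np.ptp(x) == 0:
        return BlockAverageResult(se=0.0, block_size=1, plateau_found=True,
                                  block_sizes=np.array([1]),
                                  block_ses=np.array([0.0]))
    sizes, ses = [], []
    size = 1
    while n // size >= 4:  # need >= 4 blocks for a usable variance
        nb = n // size
        means = x[: nb * size].reshape(nb, size).mean(axis=1)
        ses.append(float(np.std(means, ddof=1) / np.sqrt(nb)))
        sizes.append(size)
        size *= 2
    sizes = np.asarray(sizes)
    ses = np.asarray(ses)
    plateau_found = False
    se = ses[-1]
    block = int(sizes[-1])
    for i in range(2, len(ses)):
        c1 = abs(ses[i - 1] - ses[i - 2]) <= plateau_rtol * ses[i - 1]
        c2 = abs(ses[i] - ses[i - 1]) <= plateau_rtol * ses[i]
        if c1 and c2:
            se = ses[i]
            block = int(sizes[i])
            plateau_found = True
            break
    return BlockAverageResult(se=float(se), block_size=block,
                              plateau_found=plateau_found,
                              block_sizes=sizes, block_ses=ses)


def series_correlation(a, b) -> float:
    """Pearson correlation between two equal-length per-frame series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance series has undefined correlation")
    return float(stats.pearsonr(a, b).statistic)
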