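"""Independent slow-path oracles used to cross-check the estimators.

These deliberately avoid the implementation's code paths: the Welch oracle
uses explicit direct DFT sums (no FFT), and the wavelet oracle builds the
time-domain analytic Morlet kernel by numerical quadrature of its inverse
Fourier integral and convolves directly.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import get_window


def direct_welch(x, y, n_win, n_shift, window="hamming"):
    """Welch-averaged auto/cross spectra by explicit loops and direct DFT.

    Returns (freqs, s_xx, s_yy, s_xy, coh_sq, phase) on the one-sided grid.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = get_window(window, n_win)
    n_bins = n_win // 2 + 1
    s_xx = np.zeros(n_bins)
    s_yy = np.zeros(n_bins)
    s_xy = np.zeros(n_bins, dtype=complex)
    starts = list(range(0, len(x) - n_win + 1, n_shift))
    for s0 in starts:
        xs = x[s0 : s0 + n_win]
        ys = y[s0 : s0 + n_win]
        xs = (xs - xs.mean()) * w
        ys = (ys - ys.mean()) * w
        for k in range(n_bins):
            ek = np.exp(-2j * np.pi * k * np.arange(n_win) / n_win)
            X = np.sum(xs * ek)
            Y = np.sum(ys * ek)
            s_xx[k] += (X * np.conj(X)).real / n_win
            s_yy[k] += (Y * np.conj(Y)).real / n_win
            s_xy[k] += np.conj(X) * Y / n_win
    L = len(starts)
    s_xx /= L
    s_yy /= L
    s_xy /= L
    denom = s_xx * s_yy
    coh = np.where(denom > 0, np.abs(s_xy) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    freqs = np.arange(n_bins) / (n_win * 1.0)
    return freqs, s_xx, s_yy, s_xy, coh, np.angle(s_xy)


def morlet_time_kernel(lags_s, scale, omega0, dt, n_quad=20001):
    """Analytic Morlet kernel g(tau) by quadrature of its spectrum.

    g(tau) = (dt / 2 pi) * integral_0^inf sqrt(2 pi s / dt) * pi^(-1/4)
             * exp(-(s w - w0)^2 / 2) * exp(i w tau) dw
    so that sum_m x[m] g((m - n) dt) reproduces the frequency-domain CWT.
    """
    w_lo = max(0.0, (omega0 - 9.0) / scale)
    w_hi = (omega0 + 9.0) / scale
    w = np.linspace(w_lo, w_hi, n_quad)
    spec = np.sqrt(2 * np.pi * scale / dt) * np.pi**-0.25 * np.exp(
        -0.5 * (scale * w - omega0) ** 2
    )
    lags = np.asarray(lags_s, float)
    phase = np.exp(1j * np.outer(lags, w))
    return (dt / (2 * np.pi)) * np.trapezoid(phase * spec, w, axis=1)


def direct_cwt(x, scales, omega0, dt):
    """Time-domain convolution CWT: c(n, s) = sum_m x[m] g_s((n - m) dt)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    out = np.empty((len(scales), n), dtype=complex)
    lag_idx = np.arange(-n + 1, n)
    for j, s in enumerate(scales):
        g = morlet_time_kernel(lag_idx * dt, s, omega0, dt)
        out[j] = [np.sum(x * g[i - np.arange(n) + n - 1]) for i in range(n)]
    return out
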