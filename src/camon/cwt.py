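"""Analytic-Morlet continuous wavelet estimation of the Mayer-band phase shift.

The continuous wavelet transform is computed in the Fourier domain: the
frame's DFT is multiplied, scale by scale, by the conjugate of the analytic
Morlet weight

    psi_hat(s*w) = pi^(-1/4) * exp(-(s*w - w0)^2 / 2) * H(w),

zeroed at non-positive frequencies (Heaviside H) and normalized by
(2*pi*s/dt)^(1/2), and inverse-transformed.  Scales form a dyadic grid
s_j = s0 * 2^(j*dj) with s0 = 2*dt and dj = 1/12 (12 voices per octave);
each scale maps to the pseudo-frequency f = w0 / (2*pi*s).

Cross-spectrum, power and coherence follow the standard wavelet-coherence
construction: the pointwise cross product conj(c_x)*c_y and the two powers
are smoothed in time (Gaussian, sigma proportional to scale) and across
scales (moving average) before forming

    C(n, s) = |<conj(c_x) c_y>|^2 / (<|c_x|^2> <|c_y|^2>).

Without smoothing this ratio is identically 1 (a rank-1 identity), so the
smoothing is what gives coherence its discriminating power.  Phase uses the
same convention as the Welch back-end: positive means BFV leads BP.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .errors import InvalidArgument, InvalidConfiguration
from .framing import iter_frames
from .series import PsSample, PsTimeSeries
from .signals import SampledSignal, SignalPair

__all__ = [
    "CwtConfig",
    "ScaleGrid",
    "WaveletField",
    "WaveletCoherence",
    "build_scales",
    "morlet_fourier",
    "cwt_fft",
    "smooth_field",
    "wavelet_coherence",
    "select_mayer_scale",
    "cwt_ps_series",
    "CwtFrameEngine",
]

_EFOLD = np.sqrt(2.0)  # e-folding factor of the Morlet envelope


@dataclass(frozen=True)
class CwtConfig:
    """Parameters of the wavelet back-end.

    omega0 : center frequency of the Morlet wavelet (dimensionless, 6).
    dj : octave spacing, 1/12 = 12 voices per octave.
    s0 : smallest scale in seconds; ``None`` means 2*dt.
    time_smooth_a : Gaussian time-smoothing sigma in units of the scale
        (sigma = a * s / dt samples).
    scale_smooth_len : moving-average length along the scale axis, in scale
        bins (12 = one octave at dj = 1/12).
    pad_pow2 : zero-pad each frame to the next power of two strictly above
        its length before the DFT, reducing wrap-around.
    Frame segmentation (n_frame, n_shift, timestamp) matches the Welch
    back-end so that both emit on the same time grid.
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s0: float | None = None
    threshold: float = 0.6
    band: tuple[float, float] = (0.05, 0.15)
    time_smooth_a: float = 1.0
    scale_smooth_len: int = 12
    dt: float = 0.01
    n_frame: int = 16384
    n_shift: int = 512
    timestamp: str = "end"
    scale_criterion: str = "max"  # or "fraction"
    pad_pow2: bool = True
    agg_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise InvalidConfiguration("omega0 must be > 0")
        if not 0 < self.dj <= 1:
            raise InvalidConfiguration("dj must lie in (0, 1]")
        if self.s0 is not None and self.s0 < self.dt:
            raise InvalidConfiguration("s0 must be >= dt")
        if self.scale_smooth_len < 1:
            raise InvalidConfiguration("scale_smooth_len must be >= 1")
        if not 0 < self.threshold < 1:
            raise InvalidConfiguration("threshold must lie in (0, 1)")
        if self.time_smooth_a < 0:
            raise InvalidConfiguration("time_smooth_a must be >= 0")
        lo, hi = self.band
        if not (0 < lo < hi < 0.5 / self.dt):
            raise InvalidConfiguration("band must satisfy 0 < f_lo < f_hi < Nyquist")
        if not (1 <= self.n_shift <= self.n_frame):
            raise InvalidConfiguration("need 1 <= n_shift <= n_frame")
        if self.timestamp not in ("end", "center"):
            raise InvalidConfiguration("timestamp must be 'end' or 'center'")
        if self.scale_criterion not in ("max", "fraction"):
            raise InvalidConfiguration("scale_criterion must be 'max' or 'fraction'")
        if not 0 < self.agg_fraction <= 1:
            raise InvalidConfiguration("agg_fraction must lie in (0, 1]")

    @property
    def s0_effective(self) -> float:
        return self.s0 if self.s0 is not None else 2.0 * self.dt


@dataclass(frozen=True)
class ScaleGrid:
    """Dyadic scale grid and its pseudo-frequencies (bijective mapping)."""

    scales: np.ndarray  # s, seconds, strictly increasing
    pseudo_freqs: np.ndarray  # omega0 / (2 pi s), Hz, strictly decreasing
    omega0: float

    @property
    def n(self) -> int:
        return self.scales.size

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        idx = np.nonzero((self.pseudo_freqs >= lo) & (self.pseudo_freqs <= hi))[0]
        if idx.size == 0:
            raise InvalidConfiguration(
                f"band {band} Hz contains no grid pseudo-frequency"
            )
        return idx


def build_scales(cfg: CwtConfig, signal_length: int) -> ScaleGrid:
    """Scale grid s_j = s0 * 2^(j*dj), j = 0..J, J = floor(log2(N dt/s0)/dj)."""
    if signal_length < 2:
        raise InvalidArgument("signal_length must be >= 2")
    s0 = cfg.s0_effective
    J = int(np.floor(np.log2(signal_length * cfg.dt / s0) / cfg.dj))
    if J < 0:
        raise InvalidConfiguration("signal too short for the smallest scale")
    j = np.arange(J + 1)
    scales = s0 * 2.0 ** (j * cfg.dj)
    pfreqs = cfg.omega0 / (2.0 * np.pi * scales)
    grid = ScaleGrid(scales=scales, pseudo_freqs=pfreqs, omega0=cfg.omega0)
    grid.band_indices(cfg.band)  # raises if the band is unrepresentable
    return grid


def morlet_fourier(s, omega, omega0: float = 6.0, dt: float | None = None):
    """Fourier-domain analytic Morlet weight at scale ``s`` and frequency ``omega``.

    Returns ``pi^(-1/4) exp(-(s*omega - omega0)^2/2)`` for ``omega > 0`` and
    exactly 0 otherwise.  When ``dt`` is given, the per-scale normalization
    ``(2*pi*s/dt)^(1/2)`` is applied.
    """
    s = np.asarray(s, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(s <= 0):
        raise InvalidArgument("scale must be > 0")
    with np.errstate(over="ignore", under="ignore"):
        arg = s * omega - omega0
        w = np.pi ** -0.25 * np.exp(-0.5 * np.minimum(arg * arg, 1e6)) * (omega > 0)
    if dt is not None:
        w = w * np.sqrt(2.0 * np.pi * s / dt)
    return w


@dataclass
class WaveletField:
    """Complex wavelet coefficients on a (scale, time) lattice plus the COI.

    ``coi[n]`` is the largest trustworthy scale at time index n: cell (j, n)
    lies outside the cone of influence iff scales[j] <= coi[n] (e-folding
    distance sqrt(2)*s from the record edges).
    """

    coeffs: np.ndarray  # complex, shape (n_scales, n_time)
    scales: np.ndarray
    pseudo_freqs: np.ndarray
    dt: float
    coi: np.ndarray  # per-time maximum trustworthy scale, s

    @property
    def n_time(self) -> int:
        return self.coeffs.shape[1]

    def valid_mask(self) -> np.ndarray:
        return self.scales[:, None] <= self.coi[None, :]


def _fft_length(n: int, pad_pow2: bool) -> int:
    if not pad_pow2:
        return n
    return int(2 ** (np.floor(np.log2(n)) + 1))


def cwt_fft(
    signal: SampledSignal | np.ndarray,
    grid: ScaleGrid,
    cfg: CwtConfig,
) -> WaveletField:
    """FFT-domain CWT of one mean-centered channel on the given scale grid."""
    values = signal.values if isinstance(signal, SampledSignal) else np.asarray(signal, float)
    if values.ndim != 1 or values.size < 2:
        raise InvalidArgument("signal must be a 1-D array with >= 2 samples")
    n = values.size
    x = values - values.mean()
    m = _fft_length(n, cfg.pad_pow2)
    X = sfft.fft(x, m)
    omega = 2.0 * np.pi * sfft.fftfreq(m, cfg.dt)
    psi = morlet_fourier(grid.scales[:, None], omega[None, :], cfg.omega0, cfg.dt)
    coeffs = sfft.ifft(X[None, :] * np.conj(psi), axis=1)[:, :n]
    edge = np.minimum(np.arange(n), n - 1 - np.arange(n)) * cfg.dt
    coi = edge / _EFOLD
    return WaveletField(
        coeffs=coeffs,
        scales=grid.scales,
        pseudo_freqs=grid.pseudo_freqs,
        dt=cfg.dt,
        coi=coi,
    )


# ---------------------------------------------------------------------------
# smoothing


class _TimeSmoother:
    """Per-scale Gaussian smoothing along time, renormalized at the edges.

    Zero-padded FFT convolution divided by the smoothed all-ones mask.
    Kernels are truncated at 4 sigma.  All scales share one padded FFT
    length so whole (scale, time) blocks are transformed in single batched
    calls; kernel transforms and edge denominators are precomputed.
    """

    def __init__(self, n_time: int, sigmas: np.ndarray):
        self.n = n_time
        sigmas = np.asarray(sigmas, float)
        radii = np.where(sigmas > 0, np.ceil(4.0 * np.maximum(sigmas, 1e-300)), 0)
        self._radii = radii.astype(int)
        self._m = sfft.next_fast_len(n_time + 2 * int(self._radii.max(initial=0)))
        ones_hat = sfft.rfft(np.ones(n_time), self._m)
        ghat = np.empty((sigmas.size, self._m // 2 + 1), dtype=complex)
        denom = np.empty((sigmas.size, n_time))
        for j, (sig, r) in enumerate(zip(sigmas, self._radii)):
            if r == 0:  # sigma <= 0: identity
                ghat[j] = 1.0
                denom[j] = 1.0
                continue
            k = np.exp(-0.5 * (np.arange(-r, r + 1) / sig) ** 2)
            k /= k.sum()
            ghat[j] = sfft.rfft(k, self._m)
            denom[j] = sfft.irfft(ones_hat * ghat[j], self._m)[r : r + n_time]
        self._ghat = ghat
        self._denom = denom

    def _apply_real(self, arr: np.ndarray, ghat, radii, denom) -> np.ndarray:
        full = sfft.irfft(sfft.rfft(arr, self._m, axis=1) * ghat, self._m, axis=1)
        out = np.empty((arr.shape[0], self.n))
        for j, r in enumerate(radii):
            out[j] = full[j, r : r + self.n]
        return out / denom

    def apply_stack(self, blocks: list[np.ndarray]) -> list[np.ndarray]:
        """Smooth several same-shaped real blocks in one batched FFT call."""
        reps = len(blocks)
        if not hasattr(self, "_tiled"):
            self._tiled = {}
        if reps not in self._tiled:
            self._tiled[reps] = (
                np.tile(self._ghat, (reps, 1)),
                np.tile(self._radii, reps),
                np.tile(self._denom, (reps, 1)),
            )
        res = self._apply_real(np.concatenate(blocks), *self._tiled[reps])
        s = self._radii.size
        return [res[i * s : (i + 1) * s] for i in range(reps)]

    def apply(self, arr: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(arr):
            re, im = self.apply_stack([np.ascontiguousarray(arr.real),
                                       np.ascontiguousarray(arr.imag)])
            return re + 1j * im
        return self._apply_real(arr, self._ghat, self._radii, self._denom)


def _boxcar_scale_smooth(arr: np.ndarray, length: int) -> np.ndarray:
    """Centered moving average along the scale axis, shrunk at the edges.

    The window at bin i covers [i - length//2, i + (length-1)//2]; near the
    grid edges the average is taken over the bins actually present.
    """
    if length <= 1:
        return arr.copy()
    n = arr.shape[0]
    lo = np.maximum(np.arange(n) - length // 2, 0)
    hi = np.minimum(np.arange(n) + (length - 1) // 2, n - 1)
    csum = np.concatenate([np.zeros((1,) + arr.shape[1:], dtype=arr.dtype),
                           np.cumsum(arr, axis=0)], axis=0)
    sums = csum[hi + 1] - csum[lo]
    counts = (hi - lo + 1).astype(float)
    return sums / counts.reshape((-1,) + (1,) * (arr.ndim - 1))


def smooth_field(
    field: np.ndarray,
    grid: ScaleGrid | np.ndarray,
    cfg: CwtConfig,
    smoother: _TimeSmoother | None = None,
) -> np.ndarray:
    """Time-then-scale smoothing of a (scale, time) array.

    Time axis: Gaussian with sigma = time_smooth_a * s / dt samples at scale
    s, renormalized at the record edges (a constant field is preserved).
    Scale axis: moving average over ``scale_smooth_len`` bins with edge
    shrinkage.
    """
    scales = grid.scales if isinstance(grid, ScaleGrid) else np.asarray(grid, float)
    arr = np.asarray(field)
    if arr.ndim != 2 or arr.shape[0] != scales.size:
        raise InvalidArgument("field must have shape (n_scales, n_time)")
    if smoother is None:
        smoother = _TimeSmoother(arr.shape[1], cfg.time_smooth_a * scales / cfg.dt)
    return _boxcar_scale_smooth(smoother.apply(arr), cfg.scale_smooth_len)


# ---------------------------------------------------------------------------
# coherence


@dataclass
class WaveletCoherence:
    """Smoothed wavelet cross-spectrum, squared coherence and local phase."""

    coh_sq: np.ndarray  # (n_scales, n_time)
    phase: np.ndarray   # rad; NaN where no power
    cross: np.ndarray   # smoothed conj(c_x) * c_y
    scales: np.ndarray
    pseudo_freqs: np.ndarray
    dt: float
    coi: np.ndarray

    def valid_mask(self) -> np.ndarray:
        return self.scales[:, None] <= self.coi[None, :]


def wavelet_coherence(
    fx: WaveletField,
    fy: WaveletField,
    cfg: CwtConfig,
    smooth: bool = True,
) -> WaveletCoherence:
    """Squared coherence and phase of two wavelet fields on identical grids.

    With ``smooth=False`` the coherence degenerates to 1 wherever both
    channels have power — kept accessible as a regression probe that the
    smoothing is doing its job.
    """
    if fx.coeffs.shape != fy.coeffs.shape or not np.array_equal(fx.scales, fy.scales):
        raise InvalidArgument("wavelet fields must share grid and time base")
    cross = np.conj(fx.coeffs) * fy.coeffs
    px = fx.coeffs.real**2 + fx.coeffs.imag**2
    py = fy.coeffs.real**2 + fy.coeffs.imag**2
    if smooth:
        smoother = _TimeSmoother(
            cross.shape[1], cfg.time_smooth_a * fx.scales / cfg.dt
        )
        cross = smooth_field(cross, fx.scales, cfg, smoother)
        px = smooth_field(px, fx.scales, cfg, smoother)
        py = smooth_field(py, fx.scales, cfg, smoother)
    denom = px * py
    ok = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(ok, (cross.real**2 + cross.imag**2) / np.where(ok, denom, 1.0), 0.0)
    phase = np.where(ok, np.angle(cross), np.nan)
    return WaveletCoherence(
        coh_sq=coh,
        phase=phase,
        cross=cross,
        scales=fx.scales,
        pseudo_freqs=fx.pseudo_freqs,
        dt=fx.dt,
        coi=fx.coi,
    )


def select_mayer_scale(
    wc: WaveletCoherence,
    band: tuple[float, float],
    criterion: str = "max",
    threshold: float = 0.6,
) -> int:
    """Scale index (into the full grid) representing the Mayer band.

    ``"max"``: scale of maximal mean squared coherence over cells outside the
    cone of influence.  ``"fraction"``: scale maximizing the share of cells
    above the coherence threshold.  Ties break toward the smaller scale
    (higher pseudo-frequency).
    """
    idx = ScaleGrid(wc.scales, wc.pseudo_freqs, 0.0).band_indices(band)
    valid = wc.valid_mask()[idx]
    if not valid.any():  # degenerate short record: fall back to all cells
        valid = np.ones_like(valid, dtype=bool)
    coh = wc.coh_sq[idx]
    return int(idx[_score_scales(coh, valid, criterion, threshold)])


def _score_scales(
    coh: np.ndarray, valid: np.ndarray, criterion: str, threshold: float
) -> int:
    """Row of the band coherence block best representing the Mayer wave.

    ``max``: highest mean squared coherence over valid cells.  ``fraction``:
    highest share of suprathreshold valid cells, with mean coherence as the
    tie-break (the share saturates at 1 on strongly coherent input).
    """
    counts = valid.sum(axis=1)
    mean_coh = np.where(counts > 0, (coh * valid).sum(axis=1) / np.maximum(counts, 1), -np.inf)
    if criterion == "max":
        return int(np.argmax(mean_coh))
    if criterion != "fraction":
        raise InvalidArgument("criterion must be 'max' or 'fraction'")
    frac = np.where(
        counts > 0,
        ((coh >= threshold) & valid).sum(axis=1) / np.maximum(counts, 1),
        -np.inf,
    )
    tied = frac >= frac.max()
    return int(np.argmax(np.where(tied, mean_coh, -np.inf)))


# ---------------------------------------------------------------------------
# per-frame engine and batch pipeline


class CwtFrameEngine:
    """Per-frame wavelet estimator shared by the batch and streaming paths.

    Precomputes, for a fixed frame length, the scale grid restricted to the
    Mayer band (padded by one scale-filter length so the scale smoothing of
    band scales equals the full-grid result), the Fourier-domain wavelet
    weights, the Gaussian smoothing kernels and the COI mask.
    """

    method = "cwt"

    def __init__(self, cfg: CwtConfig, n_frame: int | None = None):
        self.cfg = cfg
        n = int(n_frame or cfg.n_frame)
        self._n = n
        grid = build_scales(cfg, n)
        bidx = grid.band_indices(cfg.band)
        # margin of half a filter window on each side keeps the scale
        # smoothing of the band rows identical to the full-grid result
        # (the centered window at row i spans [i - L//2, i + (L-1)//2])
        lo = max(int(bidx.min()) - cfg.scale_smooth_len // 2, 0)
        hi = min(int(bidx.max()) + (cfg.scale_smooth_len - 1) // 2, grid.n - 1)
        self.scales = grid.scales[lo : hi + 1]
        self.pseudo_freqs = grid.pseudo_freqs[lo : hi + 1]
        self._band_rows = bidx - lo
        m = _fft_length(n, cfg.pad_pow2)
        self._m = m
        omega = 2.0 * np.pi * sfft.fftfreq(m, cfg.dt)
        self._psi_conj = np.conj(
            morlet_fourier(self.scales[:, None], omega[None, :], cfg.omega0, cfg.dt)
        )
        self._smoother = _TimeSmoother(n, cfg.time_smooth_a * self.scales / cfg.dt)
        edge = np.minimum(np.arange(n), n - 1 - np.arange(n)) * cfg.dt
        coi = edge / _EFOLD
        coi_ok = self.scales[self._band_rows, None] <= coi[None, :]
        # the per-frame PS collapses the time axis over the frame's central
        # stripe (agg_fraction of the frame), keeping the wavelet estimate's
        # native time resolution instead of averaging the whole 163.84 s;
        # degenerate short frames fall back to the COI mask, then to all cells
        stripe = (
            np.abs(np.arange(n) - (n - 1) / 2.0) <= cfg.agg_fraction * n / 2.0
        )
        if not coi_ok.any():
            coi_ok = np.ones_like(coi_ok)
        valid = coi_ok & stripe[None, :]
        if not valid.any():
            valid = coi_ok
        self._valid_band = valid
        # the gate statistic averages over the whole COI-admissible frame:
        # a stripe-only mean has too few independent cells to reject noise
        self._gate_band = coi_ok

    @property
    def n_frame(self) -> int:
        return self._n

    @property
    def n_shift(self) -> int:
        return self.cfg.n_shift

    def _coeffs(self, v: np.ndarray) -> np.ndarray:
        x = v - v.mean()
        X = sfft.fft(x, self._m)
        return sfft.ifft(X[None, :] * self._psi_conj, axis=1, overwrite_x=True)[
            :, : self._n
        ]

    def _smooth(self, arr: np.ndarray) -> np.ndarray:
        return _boxcar_scale_smooth(self._smoother.apply(arr), self.cfg.scale_smooth_len)

    def frame_sample(self, x: np.ndarray, y: np.ndarray, time: float) -> PsSample:
        cfg = self.cfg
        cx = self._coeffs(np.asarray(x, float))
        cy = self._coeffs(np.asarray(y, float))
        raw = np.conj(cx) * cy
        box = lambda a: _boxcar_scale_smooth(a, cfg.scale_smooth_len)
        cre, cim, px, py = (
            box(b)
            for b in self._smoother.apply_stack(
                [
                    np.ascontiguousarray(raw.real),
                    np.ascontiguousarray(raw.imag),
                    cx.real**2 + cx.imag**2,
                    cy.real**2 + cy.imag**2,
                ]
            )
        )
        rows = self._band_rows
        cre, cim, px, py = cre[rows], cim[rows], px[rows], py[rows]
        cross = cre + 1j * cim
        denom = px * py
        ok = denom > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            coh_b = np.where(
                ok, (cre**2 + cim**2) / np.where(ok, denom, 1.0), 0.0
            )
        valid = self._valid_band
        counts = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if cfg.scale_criterion == "max":
                score = np.where(
                    counts > 0, (coh_b * valid).sum(axis=1) / np.maximum(counts, 1), -np.inf
                )
            else:
                score = np.where(
                    counts > 0,
                    ((coh_b >= cfg.threshold) & valid).sum(axis=1) / np.maximum(counts, 1),
                    -np.inf,
                )
        jb = int(np.argmax(score))
        j = int(rows[jb])
        f_mayer = float(self.pseudo_freqs[j])
        # frame gate: mean squared coherence over the Mayer scale's
        # COI-admissible cells must clear the threshold (a per-cell gate
        # alone would fire on isolated noise excursions)
        gcells = self._gate_band[jb]
        coh_val = float(coh_b[jb, gcells].mean()) if gcells.any() else 0.0
        cells = valid[jb] & (coh_b[jb] >= cfg.threshold)
        if not cells.any():  # gate passed but the stripe is subthreshold
            cells = gcells & (coh_b[jb] >= cfg.threshold)
        if coh_val >= cfg.threshold and cells.any():
            ph = np.angle(cross[jb, cells])
            phase = float(np.angle(np.mean(np.exp(1j * ph))))
            return PsSample(
                time=time, f_mayer=f_mayer, coh_sq=coh_val, phase=phase, gated=False
            )
        return PsSample(
            time=time, f_mayer=f_mayer, coh_sq=coh_val, phase=None, gated=True
        )


def cwt_ps_series(
    pair: SignalPair, cfg: CwtConfig | None = None, channel: str = "left"
) -> PsTimeSeries:
    """Run the full wavelet pipeline over a recording, one sample per frame advance.

    Per frame: CWT of both channels, time/scale smoothing, squared coherence,
    Mayer-scale selection, threshold gating, and the phase shift as the
    circular mean of the suprathreshold in-band phase cells outside the cone
    of influence.
    """
    cfg = cfg or CwtConfig()
    engine = CwtFrameEngine(cfg)
    samples = [
        engine.frame_sample(fr.x, fr.y, fr.time)
        for fr in iter_frames(
            pair.bp.values,
            pair.bfv(channel).values,
            cfg.n_frame,
            cfg.n_shift,
            cfg.dt,
            pair.t0,
            cfg.timestamp,
        )
    ]
    return PsTimeSeries.from_samples(samples, method="cwt", channel=channel)
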