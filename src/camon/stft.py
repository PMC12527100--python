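"""Welch-averaged short-time Fourier estimation of the Mayer-band phase shift.

Each frame of ``n_frame`` samples is divided into tapered windows of
``n_win`` samples advancing by ``n_shift``; per window the channels are
mean-centered, tapered and transformed, and the auto/cross spectra are
averaged over all windows fully inside the frame.  The squared coherence

    C(k) = |S_xy(k)|^2 / (S_xx(k) S_yy(k))

selects the Mayer frequency (argmax over the 0.05-0.15 Hz band) and gates the
phase estimate: a frame emits a phase only where C(k_M) >= threshold.  The
sign convention is S_xy = conj(X) * Y with x = BP, y = BFV, so a positive
phase means BFV leads BP (intact autoregulation ~ +1 rad).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .errors import InvalidArgument, InvalidConfiguration
from .framing import iter_frames
from .series import PsSample, PsTimeSeries
from .signals import SignalPair

__all__ = [
    "StftConfig",
    "SpectralEstimate",
    "frame_stream",
    "welch_cross_spectra",
    "pick_mayer_frequency",
    "stft_ps_series",
    "StftFrameEngine",
]


@dataclass(frozen=True)
class StftConfig:
    """Parameters of the Welch back-end.

    Defaults follow the published configuration: 163.84 s frames
    (16384 samples at 0.01 s), 20.48 s Hamming windows (2048 samples)
    advancing by 512 samples (5.12 s), coherence gate 0.6, Mayer band
    0.05-0.15 Hz.
    """

    n_frame: int = 16384
    n_win: int = 2048
    n_shift: int = 512
    window: str = "hamming"
    threshold: float = 0.6
    band: tuple[float, float] = (0.05, 0.15)
    dt: float = 0.01
    timestamp: str = "end"  # or "center"

    def __post_init__(self) -> None:
        if not (1 <= self.n_shift <= self.n_win <= self.n_frame):
            raise InvalidConfiguration(
                "need 1 <= n_shift <= n_win <= n_frame, got "
                f"shift={self.n_shift} win={self.n_win} frame={self.n_frame}"
            )
        if not 0 < self.threshold < 1:
            raise InvalidConfiguration("threshold must lie in (0, 1)")
        lo, hi = self.band
        if not (0 < lo < hi < 0.5 / self.dt):
            raise InvalidConfiguration("band must satisfy 0 < f_lo < f_hi < Nyquist")
        if self.timestamp not in ("end", "center"):
            raise InvalidConfiguration("timestamp must be 'end' or 'center'")

    @property
    def frame_duration(self) -> float:
        return self.n_frame * self.dt

    @property
    def win_duration(self) -> float:
        return self.n_win * self.dt

    @property
    def freq_resolution(self) -> float:
        """DFT bin spacing 1/(n_win * dt); 0.0488 Hz with defaults."""
        return 1.0 / (self.n_win * self.dt)

    @property
    def n_windows(self) -> int:
        """Windows fully inside a frame (29 with defaults)."""
        return (self.n_frame - self.n_win) // self.n_shift + 1


@dataclass
class SpectralEstimate:
    """Frame-averaged one-sided auto/cross spectra and derived quantities."""

    freqs: np.ndarray
    s_xx: np.ndarray
    s_yy: np.ndarray
    s_xy: np.ndarray
    coh_sq: np.ndarray
    phase: np.ndarray
    frame_time: float = 0.0  # frame center, s


def frame_stream(pair: SignalPair, cfg: StftConfig, channel: str = "left"):
    """Yield sliding frames of the pair (BP vs the chosen BFV channel)."""
    return iter_frames(
        pair.bp.values,
        pair.bfv(channel).values,
        cfg.n_frame,
        cfg.n_shift,
        cfg.dt,
        pair.t0,
        cfg.timestamp,
    )


def _segment(values: np.ndarray, n_win: int, n_shift: int) -> np.ndarray:
    starts = np.arange(0, len(values) - n_win + 1, n_shift)
    segs = np.stack([values[s : s + n_win] for s in starts])
    return segs - segs.mean(axis=1, keepdims=True)


def welch_cross_spectra(
    x: np.ndarray, y: np.ndarray, cfg: StftConfig, frame_time: float = 0.0
) -> SpectralEstimate:
    """Average windowed auto/cross spectra over one frame.

    Per window: mean-center, taper, DFT; S_xx = |X|^2/N_win,
    S_yy = |Y|^2/N_win, S_xy = conj(X) Y / N_win; then average across the
    windows fully inside the frame.  Bins with zero averaged power in either
    channel get squared coherence 0 (not NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgument("x and y must be equal-length 1-D arrays")
    if len(x) != cfg.n_frame:
        raise InvalidArgument(
            f"frame length {len(x)} does not match n_frame={cfg.n_frame}"
        )
    w = get_window(cfg.window, cfg.n_win)
    X = np.fft.rfft(_segment(x, cfg.n_win, cfg.n_shift) * w, axis=1)
    Y = np.fft.rfft(_segment(y, cfg.n_win, cfg.n_shift) * w, axis=1)
    s_xx = (np.abs(X) ** 2).mean(axis=0) / cfg.n_win
    s_yy = (np.abs(Y) ** 2).mean(axis=0) / cfg.n_win
    s_xy = (np.conj(X) * Y).mean(axis=0) / cfg.n_win
    denom = s_xx * s_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh_sq = np.where(denom > 0, np.abs(s_xy) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    phase = np.angle(s_xy)
    freqs = np.fft.rfftfreq(cfg.n_win, cfg.dt)
    return SpectralEstimate(
        freqs=freqs,
        s_xx=s_xx,
        s_yy=s_yy,
        s_xy=s_xy,
        coh_sq=coh_sq,
        phase=phase,
        frame_time=frame_time,
    )


def pick_mayer_frequency(
    est: SpectralEstimate, band: tuple[float, float]
) -> int:
    """Bin of maximal squared coherence within the Mayer band.

    Ties break toward the lower frequency (first argmax).
    """
    lo, hi = band
    idx = np.nonzero((est.freqs >= lo) & (est.freqs <= hi))[0]
    if idx.size == 0:
        raise InvalidConfiguration(
            f"band {band} contains no DFT bin at resolution "
            f"{est.freqs[1] - est.freqs[0]:.4g} Hz"
        )
    return int(idx[np.argmax(est.coh_sq[idx])])


class StftFrameEngine:
    """Per-frame Welch estimator reused by the batch and streaming paths."""

    method = "stft"

    def __init__(self, cfg: StftConfig):
        self.cfg = cfg
        # validate that the band is non-empty up front
        freqs = np.fft.rfftfreq(cfg.n_win, cfg.dt)
        lo, hi = cfg.band
        if not np.any((freqs >= lo) & (freqs <= hi)):
            raise InvalidConfiguration("Mayer band contains no DFT bin")

    @property
    def n_frame(self) -> int:
        return self.cfg.n_frame

    @property
    def n_shift(self) -> int:
        return self.cfg.n_shift

    def frame_sample(self, x: np.ndarray, y: np.ndarray, time: float) -> PsSample:
        est = welch_cross_spectra(x, y, self.cfg)
        k = pick_mayer_frequency(est, self.cfg.band)
        coh = float(est.coh_sq[k])
        gated = coh < self.cfg.threshold
        return PsSample(
            time=time,
            f_mayer=float(est.freqs[k]),
            coh_sq=coh,
            phase=None if gated else float(est.phase[k]),
            gated=gated,
        )


def stft_ps_series(
    pair: SignalPair, cfg: StftConfig | None = None, channel: str = "left"
) -> PsTimeSeries:
    """Run the full Welch pipeline over a recording: one sample per frame advance."""
    cfg = cfg or StftConfig()
    engine = StftFrameEngine(cfg)
    samples = [
        engine.frame_sample(fr.x, fr.y, fr.time) for fr in frame_stream(pair, cfg, channel)
    ]
    return PsTimeSeries.from_samples(samples, method="stft", channel=channel)
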