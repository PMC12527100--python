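"""Streaming front-end: ring buffer + per-frame estimator, bounded latency.

The engine keeps the newest ``n_frame`` samples per channel and re-runs the
chosen back-end every ``n_shift`` new samples once warm.  An emission depends
only on samples up to its frame end, so the warm-up delay equals one frame
duration (163.84 s with defaults) and every emission thereafter arrives every
n_shift * dt seconds.  Feeding a recording through :func:`run_replay` in any
chunk size reproduces the batch estimator's output bit for bit, because both
paths share the same per-frame code.
"""
from __future__ import annotations

import numpy as np

from .cwt import CwtConfig, CwtFrameEngine
from .errors import InvalidArgument
from .framing import frame_time
from .series import PsSample, PsTimeSeries
from .signals import SignalPair
from .stft import StftConfig, StftFrameEngine


def _make_engine(cfg, backend: str):
    if backend == "stft":
        if not isinstance(cfg, StftConfig):
            raise InvalidArgument("stft backend needs an StftConfig")
        return StftFrameEngine(cfg)
    if backend == "cwt":
        if not isinstance(cfg, CwtConfig):
            raise InvalidArgument("cwt backend needs a CwtConfig")
        return CwtFrameEngine(cfg)
    raise InvalidArgument(f"unknown backend {backend!r}")


class StreamingEstimator:
    """Push synchronized BP/BFV chunks, receive phase-shift samples.

    Parameters
    ----------
    cfg : StftConfig or CwtConfig
        Back-end configuration; frame geometry and timestamps come from here.
    backend : {"stft", "cwt"}
    t0 : float
        Time of the first streamed sample, seconds.
    """

    def __init__(self, cfg, backend: str = "stft", t0: float = 0.0):
        self.cfg = cfg
        self.backend = backend
        self.t0 = t0
        self._engine = _make_engine(cfg, backend)
        n = self._engine.n_frame
        self._nf = n
        self._ns = self._engine.n_shift
        self._buf = np.zeros((2, n))
        self._pos = 0  # next write position in the ring
        self.samples_seen = 0
        self._next_end = n  # absolute sample index of the next frame end

    def _ordered(self, row: int) -> np.ndarray:
        # frame in chronological order; a copy, like a batch slice
        if self._pos == 0:
            return self._buf[row].copy()
        return np.concatenate([self._buf[row, self._pos :], self._buf[row, : self._pos]])

    def _write(self, bp: np.ndarray, bfv: np.ndarray) -> None:
        k = len(bp)
        if k >= self._nf:  # only the newest n_frame samples matter
            self._buf[0] = bp[-self._nf :]
            self._buf[1] = bfv[-self._nf :]
            self._pos = 0
            return
        first = min(k, self._nf - self._pos)
        self._buf[0, self._pos : self._pos + first] = bp[:first]
        self._buf[1, self._pos : self._pos + first] = bfv[:first]
        rest = k - first
        if rest:
            self._buf[0, :rest] = bp[first:]
            self._buf[1, :rest] = bfv[first:]
        self._pos = (self._pos + k) % self._nf

    def push(self, bp, bfv) -> list[PsSample]:
        """Append new synchronized samples; return any freshly due PS samples."""
        bp = np.atleast_1d(np.asarray(bp, dtype=float))
        bfv = np.atleast_1d(np.asarray(bfv, dtype=float))
        if bp.shape != bfv.shape or bp.ndim != 1:
            raise InvalidArgument("bp and bfv chunks must be equal-length 1-D")
        out: list[PsSample] = []
        i, n = 0, len(bp)
        while i < n:
            take = min(n - i, self._next_end - self.samples_seen)
            self._write(bp[i : i + take], bfv[i : i + take])
            self.samples_seen += take
            i += take
            if self.samples_seen == self._next_end:
                start = self._next_end - self._nf
                t = frame_time(start, self._nf, self.cfg.dt, self.t0, self.cfg.timestamp)
                out.append(
                    self._engine.frame_sample(self._ordered(0), self._ordered(1), t)
                )
                self._next_end += self._ns
        return out


def run_replay(
    pair: SignalPair,
    cfg,
    backend: str = "stft",
    chunk_size: int = 4096,
    channel: str = "left",
) -> PsTimeSeries:
    """Stream a recording through the real-time engine in fixed-size chunks.

    The result equals the batch estimator's series exactly (same floats) for
    any chunk size >= 1.  An empty recording yields an empty series.
    """
    if chunk_size < 1:
        raise InvalidArgument("chunk_size must be >= 1")
    est = StreamingEstimator(cfg, backend=backend, t0=pair.t0)
    bp = pair.bp.values
    bfv = pair.bfv(channel).values
    samples: list[PsSample] = []
    for i in range(0, len(bp), chunk_size):
        samples.extend(est.push(bp[i : i + chunk_size], bfv[i : i + chunk_size]))
    return PsTimeSeries.from_samples(samples, method=backend, channel=channel)
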