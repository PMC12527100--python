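"""Phase-shift time series: the common output type of both estimator back-ends.

Each analysis frame yields one :class:`PsSample`.  Frames whose squared
coherence at the selected Mayer frequency falls below the gate threshold are
*gated*: they keep their timestamp and coherence but carry no phase, so that
downstream gap statistics remain computable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class PsSample:
    """One frame's phase-shift estimate.

    ``phase`` is ``None`` exactly when ``gated`` is true, i.e. when the squared
    coherence at the picked Mayer frequency stayed below the threshold.
    Positive phase means BFV leads BP (intact autoregulation ~ +1 rad).
    """

    time: float
    f_mayer: float
    coh_sq: float
    phase: float | None
    gated: bool

    def __post_init__(self) -> None:
        if self.gated != (self.phase is None):
            raise ValueError("phase must be present iff the sample is not gated")


@dataclass
class PsTimeSeries:
    """Ordered phase-shift samples from one estimator run on one channel.

    ``phase`` uses NaN for gated samples; ``times`` are strictly increasing
    and uniformly spaced (one sample per frame advance).
    """

    times: np.ndarray
    f_mayer: np.ndarray
    coh_sq: np.ndarray
    phase: np.ndarray
    method: str = ""
    channel: str = "left"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_mayer = np.asarray(self.f_mayer, dtype=float)
        self.coh_sq = np.asarray(self.coh_sq, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        n = self.times.size
        if not (self.f_mayer.size == self.coh_sq.size == self.phase.size == n):
            raise ValueError("all series columns must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_samples(
        cls, samples: Iterable[PsSample], method: str = "", channel: str = "left"
    ) -> "PsTimeSeries":
        samples = list(samples)
        return cls(
            times=np.array([s.time for s in samples], dtype=float),
            f_mayer=np.array([s.f_mayer for s in samples], dtype=float),
            coh_sq=np.array([s.coh_sq for s in samples], dtype=float),
            phase=np.array(
                [np.nan if s.phase is None else s.phase for s in samples], dtype=float
            ),
            method=method,
            channel=channel,
        )

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def gated(self) -> np.ndarray:
        return np.isnan(self.phase)

    def samples(self) -> list[PsSample]:
        return [
            PsSample(
                time=float(t),
                f_mayer=float(f),
                coh_sq=float(c),
                phase=None if np.isnan(p) else float(p),
                gated=bool(np.isnan(p)),
            )
            for t, f, c, p in zip(self.times, self.f_mayer, self.coh_sq, self.phase)
        ]

    def ungated(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and phases of the samples that passed the coherence gate."""
        keep = ~self.gated
        return self.times[keep], self.phase[keep]
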