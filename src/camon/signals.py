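"""In-memory containers for uniformly sampled hemodynamic signals.

Arterial blood pressure (BP, mmHg) and cerebral blood flow velocity (BFV,
cm/s in the middle cerebral artery) are acquired synchronously at a fixed
sampling interval (0.01 s by default).  :class:`SampledSignal` holds one
channel; :class:`SignalPair` holds the synchronized BP + BFV channel(s)
sharing a common time base.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgument

DEFAULT_DT = 0.01  # s


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    values : array-like
        Sample values (mmHg for BP, cm/s for BFV).
    dt : float
        Sampling interval in seconds, > 0.
    t0 : float
        Time of the first sample, seconds.
    units : str
        Unit label, informational only.
    """

    values: np.ndarray
    dt: float = DEFAULT_DT
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise InvalidArgument("signal must be a non-empty 1-D sequence")
        if not self.dt > 0:
            raise InvalidArgument(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt


@dataclass(frozen=True)
class SignalPair:
    """Synchronized BP and one or two (left/right MCA) BFV channels."""

    bp: SampledSignal
    bfv_left: SampledSignal
    bfv_right: SampledSignal | None = None

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if ch.n != self.bp.n:
                raise InvalidArgument(f"channel {name!r} length differs from BP")
            if ch.dt != self.bp.dt:
                raise InvalidArgument(f"channel {name!r} dt differs from BP")
            if ch.t0 != self.bp.t0:
                raise InvalidArgument(f"channel {name!r} t0 differs from BP")

    @property
    def channels(self) -> dict[str, SampledSignal]:
        out = {"left": self.bfv_left}
        if self.bfv_right is not None:
            out["right"] = self.bfv_right
        return out

    def bfv(self, channel: str = "left") -> SampledSignal:
        try:
            return self.channels[channel]
        except KeyError:
            raise InvalidArgument(f"no BFV channel {channel!r}") from None

    @property
    def dt(self) -> float:
        return self.bp.dt

    @property
    def t0(self) -> float:
        return self.bp.t0

    @property
    def n(self) -> int:
        return self.bp.n
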