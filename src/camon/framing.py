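"""Sliding-frame segmentation shared by both estimator back-ends.

Frames of ``n_frame`` samples advance by ``n_shift`` samples; a partial final
advance is dropped.  Frame count for a record of length L is
``(L - n_frame) // n_shift + 1``.
"""
from __future__ import annotations

from typing import Iterator, NamedTuple

import numpy as np

from .errors import TooShortError


class Frame(NamedTuple):
    start: int          # index of the first sample in the frame
    time: float         # emission timestamp per the configured convention
    time_center: float  # frame-center time (spectral estimate timestamp)
    x: np.ndarray       # BP samples
    y: np.ndarray       # BFV samples


def n_frames(length: int, n_frame: int, n_shift: int) -> int:
    if length < n_frame:
        return 0
    return (length - n_frame) // n_shift + 1


def frame_time(start: int, n_frame: int, dt: float, t0: float, timestamp: str) -> float:
    # "end": PS as of now, computed over the trailing frame; "center": midpoint.
    if timestamp == "end":
        return t0 + (start + n_frame) * dt
    if timestamp == "center":
        return t0 + (start + n_frame / 2.0) * dt
    raise ValueError(f"unknown timestamp convention {timestamp!r}")


def iter_frames(
    x: np.ndarray,
    y: np.ndarray,
    n_frame: int,
    n_shift: int,
    dt: float,
    t0: float = 0.0,
    timestamp: str = "end",
) -> Iterator[Frame]:
    if len(x) != len(y):
        raise ValueError("channels must have equal length")
    if len(x) < n_frame:
        raise TooShortError(
            f"signal length {len(x)} is shorter than one frame ({n_frame} samples)"
        )
    for k in range(n_frames(len(x), n_frame, n_shift)):
        start = k * n_shift
        yield Frame(
            start=start,
            time=frame_time(start, n_frame, dt, t0, timestamp),
            time_center=frame_time(start, n_frame, dt, t0, "center"),
            x=x[start : start + n_frame],
            y=y[start : start + n_frame],
        )
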