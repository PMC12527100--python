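"""Summary metrics for autoregulation reactivity and estimator performance.

Phase statistics are circular throughout (angles are averaged via the
resultant vector), so means are immune to wrap artifacts near +-pi.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientCoherenceError, InvalidArgument
from .series import PsTimeSeries
from .simulate import ThetaProfile

__all__ = [
    "circular_mean",
    "EtaResult",
    "sensitivity_eta",
    "coherent_fraction",
    "recovery_report",
]


def circular_mean(phases: np.ndarray) -> float:
    """Angle of the mean resultant vector of the given phases (rad)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise InvalidArgument("cannot take the circular mean of no phases")
    return float(np.angle(np.mean(np.exp(1j * phases))))


def _median3(x: np.ndarray) -> np.ndarray:
    """3-sample running median with edge clamping; suppresses single spikes."""
    if x.size < 3:
        return x.copy()
    pad = np.concatenate([x[:1], x, x[-1:]])
    return np.median(np.lib.stride_tricks.sliding_window_view(pad, 3), axis=1)


def _in_interval(times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    a, b = interval
    if not b > a:
        raise InvalidArgument("interval must satisfy t_end > t_start")
    return (times >= a) & (times <= b)


@dataclass(frozen=True)
class EtaResult:
    """Relative phase-shift sensitivity eta = (theta_ext - theta_bar)/theta_bar."""

    theta_bar: float  # baseline mean PS, rad
    theta_ext: float  # extremal PS inside the test interval, rad
    eta: float


def sensitivity_eta(
    series: PsTimeSeries,
    baseline: tuple[float, float],
    test: tuple[float, float],
    mode: str = "min",
) -> EtaResult:
    """Reactivity of the phase shift to a standardized load.

    ``theta_bar`` is the circular mean of ungated phases in the baseline
    interval; ``theta_ext`` the minimum (hypercapnia) or maximum
    (hypocapnia) of the median-smoothed ungated phases in the test interval.
    A hypercapnic drop gives eta < 0, a hypocapnic rise eta > 0 (for a
    positive baseline).
    """
    if mode not in ("min", "max"):
        raise InvalidArgument("mode must be 'min' or 'max'")
    times, phases = series.ungated()
    base = _in_interval(times, baseline)
    if not base.any():
        raise InsufficientCoherenceError("no ungated samples in the baseline interval")
    theta_bar = circular_mean(phases[base])
    if theta_bar == 0:
        raise InvalidArgument("baseline mean phase is zero; eta undefined")
    tmask = _in_interval(times, test)
    if not tmask.any():
        raise InsufficientCoherenceError("no ungated samples in the test interval")
    smoothed = _median3(phases)[tmask]
    theta_ext = float(smoothed.min() if mode == "min" else smoothed.max())
    return EtaResult(
        theta_bar=theta_bar,
        theta_ext=theta_ext,
        eta=(theta_ext - theta_bar) / theta_bar,
    )


def coherent_fraction(series: PsTimeSeries) -> float:
    """Share of samples that passed the coherence gate (phase present)."""
    if series.n == 0:
        raise InvalidArgument("coherent_fraction of an empty series")
    return float(np.mean(~series.gated))


def _step_fit_time(times: np.ndarray, values: np.ndarray, a: float, b: float):
    """Least-squares fit of a step from level ``a`` to level ``b``.

    Scans every boundary between consecutive samples and minimizes the sum of
    squared residuals against the two plateau levels; returns the midpoint of
    the best boundary.  Far more noise-robust than a first-crossing rule.
    """
    if times.size < 2:
        return None
    ra = np.concatenate([[0.0], np.cumsum((values - a) ** 2)])
    rb = np.concatenate([[0.0], np.cumsum((values - b) ** 2)])
    # boundary k: samples [0, k) on level a, [k, n) on level b
    sse = ra[:-1] + (rb[-1] - rb[:-1])
    k = int(np.argmin(sse))
    if k == 0:
        return float(times[0])
    if k >= times.size:
        return float(times[-1])
    return float(0.5 * (times[k - 1] + times[k]))


def recovery_report(
    series: PsTimeSeries,
    truth: ThetaProfile,
    plateau_margin: float = 0.0,
) -> dict[str, float]:
    """Compare an estimated PS series against the simulator's ground truth.

    Returns ``bias`` and ``rmse`` over ungated samples on plateaus (ramps,
    widened by ``plateau_margin`` seconds, are excluded) and, when the truth
    contains a level change, ``localization_error_s``: the absolute distance
    between the estimated transition midpoint (first crossing of the mid
    level by the median-smoothed series) and the true transition time.
    Series computed with the frame-center timestamp convention give the
    meaningful localization comparison.
    """
    times, phases = series.ungated()
    if times.size == 0:
        raise InsufficientCoherenceError("series contains no ungated samples")
    plateau = truth.plateau_mask(times, margin=plateau_margin)
    if not plateau.any():
        raise InvalidArgument("no ungated samples fall on a truth plateau")
    err = np.angle(np.exp(1j * (phases[plateau] - truth(times[plateau]))))
    out: dict[str, float] = {
        "bias": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "n_plateau": int(plateau.sum()),
    }
    transitions = [
        (t, a, b) for (t, a, b) in truth.transitions() if times[0] <= t <= times[-1]
    ]
    if transitions:
        t_true, a, b = transitions[0]
        # fit a single step on the stretch up to the following transition
        t_stop = transitions[1][0] if len(transitions) > 1 else np.inf
        seg = times < t_stop
        t_est = _step_fit_time(times[seg], _median3(phases)[seg], a, b)
        out["localization_error_s"] = (
            float("nan") if t_est is None else abs(t_est - t_true)
        )
    return out
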