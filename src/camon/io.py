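"""CSV carriers, scenario files and metric dumps.

Pair CSV dialect: header ``time_s,abp_mmhg,bfv_left_cms[,bfv_right_cms]``,
one row per sample on a uniform time grid.  PS CSV dialect: header
``time_s,channel,method,f_mayer_hz,coh_sq,phase_rad`` with an empty
``phase_rad`` cell for gated samples.  Scenario files are flat YAML
key/value mappings (θ events as a list of mappings).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GapTooLongError, HeaderError, InvalidArgument, NonUniformGridError
from .series import PsTimeSeries
from .signals import SampledSignal, SignalPair
from .simulate import SimulationSpec, ThetaSegment, build_theta_profile

log = logging.getLogger("camon")

PAIR_COLUMNS = ("time_s", "abp_mmhg", "bfv_left_cms", "bfv_right_cms")
PS_COLUMNS = ("time_s", "channel", "method", "f_mayer_hz", "coh_sq", "phase_rad")

_GRID_TOL = 1e-6  # s


def write_pair_csv(pair: SignalPair, path) -> None:
    cols = {
        "time_s": pair.bp.times,
        "abp_mmhg": pair.bp.values,
        "bfv_left_cms": pair.bfv_left.values,
    }
    if pair.bfv_right is not None:
        cols["bfv_right_cms"] = pair.bfv_right.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_pair_csv(path, max_gap_s: float = 0.5) -> SignalPair:
    """Read and validate a pair CSV.

    The sampling interval is inferred from the time column.  Missing rows or
    NaN cells spanning at most ``max_gap_s`` seconds are linearly
    interpolated (logged); anything longer raises :class:`GapTooLongError`.
    Time stamps off the uniform grid raise :class:`NonUniformGridError`.
    """
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    if cols[:3] != PAIR_COLUMNS[:3] or (len(cols) > 3 and cols[3] != PAIR_COLUMNS[3]):
        raise HeaderError(f"expected header {PAIR_COLUMNS[:3]}..., got {cols}")
    if len(df) < 2:
        raise InvalidArgument("pair CSV needs at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    if np.isnan(t).any():
        raise NonUniformGridError("time column contains missing values")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise NonUniformGridError("time stamps must be strictly increasing")
    dt = float(np.median(steps))
    ratio = steps / dt
    k = np.round(ratio)
    if np.any(np.abs(steps - k * dt) > _GRID_TOL):
        raise NonUniformGridError(
            "time stamps do not lie on a uniform grid (tolerance 1e-6 s)"
        )
    # re-index onto the full grid, opening NaN gaps where rows are missing
    idx = np.round((t - t[0]) / dt).astype(int)
    n = idx[-1] + 1
    data = {}
    for col in df.columns[1:]:
        full = np.full(n, np.nan)
        full[idx] = df[col].to_numpy(dtype=float)
        data[col] = full
    max_gap = int(np.floor(max_gap_s / dt))
    for col, v in data.items():
        isnan = np.isnan(v)
        if not isnan.any():
            continue
        if isnan[0] or isnan[-1]:
            raise GapTooLongError(f"column {col!r} starts or ends with missing data")
        # run lengths of NaN stretches
        edges = np.flatnonzero(np.diff(isnan.astype(int)))
        starts = edges[::2] + 1
        ends = edges[1::2] + 1
        longest = int((ends - starts).max())
        if longest > max_gap:
            raise GapTooLongError(
                f"column {col!r} has a {longest * dt:.3g}s gap "
                f"(> {max_gap_s:.3g}s policy limit)"
            )
        good = ~isnan
        v[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), v[good])
        log.warning(
            "interpolated %d missing samples (longest gap %.3gs) in %s",
            int(isnan.sum()), longest * dt, col,
        )
    t0 = float(t[0])
    bp = SampledSignal(data["abp_mmhg"], dt=dt, t0=t0, units="mmHg")
    left = SampledSignal(data["bfv_left_cms"], dt=dt, t0=t0, units="cm/s")
    right = None
    if "bfv_right_cms" in data:
        right = SampledSignal(data["bfv_right_cms"], dt=dt, t0=t0, units="cm/s")
    return SignalPair(bp=bp, bfv_left=left, bfv_right=right)


def write_ps_csv(series_list, path) -> None:
    """Write one or more PS series (e.g. left and right channels) to one CSV."""
    if isinstance(series_list, PsTimeSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "channel": s.channel,
                    "method": s.method,
                    "f_mayer_hz": s.f_mayer,
                    "coh_sq": s.coh_sq,
                    "phase_rad": s.phase,  # NaN -> empty cell
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_ps_csv(path) -> list[PsTimeSeries]:
    df = pd.read_csv(path)
    if tuple(df.columns) != PS_COLUMNS:
        raise HeaderError(f"expected header {PS_COLUMNS}, got {tuple(df.columns)}")
    out = []
    for (channel, method), grp in df.groupby(["channel", "method"], sort=False):
        out.append(
            PsTimeSeries(
                times=grp["time_s"].to_numpy(float),
                f_mayer=grp["f_mayer_hz"].to_numpy(float),
                coh_sq=grp["coh_sq"].to_numpy(float),
                phase=grp["phase_rad"].to_numpy(float),
                method=str(method),
                channel=str(channel),
            )
        )
    return out


def write_coherence_map(wc, path, decimate: int = 1) -> None:
    """Long-format CSV export of a wavelet coherence field for plotting.

    Columns ``time_s,scale_s,pseudo_freq_hz,coh_sq,phase_rad``, one row per
    (time, scale) cell; ``decimate`` keeps every k-th time sample.
    """
    n_scales, n_time = wc.coh_sq.shape
    tidx = np.arange(0, n_time, max(1, int(decimate)))
    times = tidx * wc.dt
    rows = {
        "time_s": np.tile(times, n_scales),
        "scale_s": np.repeat(wc.scales, times.size),
        "pseudo_freq_hz": np.repeat(wc.pseudo_freqs, times.size),
        "coh_sq": wc.coh_sq[:, tidx].ravel(),
        "phase_rad": wc.phase[:, tidx].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def load_scenario(path) -> SimulationSpec:
    """Build a SimulationSpec from a flat YAML scenario file.

    Recognized keys: duration, dt, seed, mayer_frequency, noise_sd_bp,
    noise_sd_bfv, baseline_bp, baseline_bfv, bilateral, theta_baseline and
    theta_events (list of {t_start, t_end, theta, ramp}).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidArgument("scenario file must be a YAML mapping")
    theta = build_theta_profile(
        float(raw.pop("theta_baseline", 0.98)),
        [ThetaSegment(**ev) for ev in raw.pop("theta_events", [])],
    )
    try:
        return SimulationSpec(theta=theta, **raw)
    except TypeError as exc:
        raise InvalidArgument(f"bad scenario key: {exc}") from None


def dump_metrics(metrics: dict, path) -> None:
    """Flat key/value metrics file (one `key = value` line each)."""
    lines = [f"{k} = {v:.6g}" if isinstance(v, float) else f"{k} = {v}"
             for k, v in metrics.items()]
    Path(path).write_text("\n".join(lines) + "\n")
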