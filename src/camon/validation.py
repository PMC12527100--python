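"""Synthetic validation experiments for both estimator back-ends.

Every routine here builds its own seeded synthetic recordings, runs the
published pipeline on them and measures the outcome, so the numbers are
recomputed from scratch on every call.  Problem sizes are desk-scale:
plateau-recovery records of 200 s per phase level and step-localization
records of 480 s, with 20 seeds each.
"""
from __future__ import annotations

import numpy as np

from .cwt import CwtConfig, CwtFrameEngine, cwt_ps_series
from .metrics import circular_mean, coherent_fraction, recovery_report, sensitivity_eta
from .realtime import run_replay
from .simulate import SimulationSpec, ThetaProfile, ThetaSegment, capnia_protocol, simulate_pair
from .stft import StftConfig, StftFrameEngine, stft_ps_series

#: The anchor phase-shift levels used as simulation ground truth (rad):
#: healthy baseline, hypercapnic minimum, hypocapnic maximum.
ANCHOR_THETAS = {"baseline": 0.98, "hypercapnia": 0.45, "hypocapnia": 1.37}


def _child_seed(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def _series(pair, cfg, backend):
    return stft_ps_series(pair, cfg) if backend == "stft" else cwt_ps_series(pair, cfg)


def configuration_arithmetic(cfg: StftConfig | None = None) -> dict[str, float]:
    """Printed-parameter arithmetic of the default Welch configuration."""
    cfg = cfg or StftConfig()
    bin_spacing = cfg.freq_resolution
    return {
        "frame_duration_s": cfg.frame_duration,
        "window_duration_s": cfg.win_duration,
        # bin spacing truncated to three decimals, as printed
        "stft_bin_spacing_hz": np.trunc(bin_spacing * 1000) / 1000,
        "windows_per_frame_quotient": cfg.n_frame // cfg.n_shift,
    }


def self_coherence(seed: int = 0, n_frame: int = 16384) -> dict[str, float]:
    """Feed one channel to both inputs; report in-band coherence and |phase|.

    Identity check: squared coherence must be 1 and phase 0 at every bin or
    cell with power, for both back-ends.
    """
    spec = SimulationSpec(duration=n_frame * 0.01, seed=_child_seed(seed, 0))
    x = simulate_pair(spec).bp.values
    t_end = len(x) * 0.01
    scfg = StftConfig(n_frame=n_frame)
    s = StftFrameEngine(scfg).frame_sample(x, x, t_end)
    ccfg = CwtConfig(n_frame=n_frame)
    c = CwtFrameEngine(ccfg).frame_sample(x, x, t_end)
    return {
        "stft_coh_sq": s.coh_sq,
        "stft_abs_phase": abs(s.phase),
        "cwt_coh_sq": c.coh_sq,
        "cwt_abs_phase": abs(c.phase),
    }


def plateau_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    duration: float = 700.0,
    thetas: dict[str, float] = ANCHOR_THETAS,
    backends: tuple[str, ...] = ("stft", "cwt"),
) -> dict[str, dict]:
    """Recover constant phase-shift plateaus at default SNR.

    For every seed and plateau level a fresh recording is synthesized with a
    constant true θ and both back-ends estimate it; the per-record estimate
    is the circular mean of ungated phases.  Records span 700 s, comparable
    to one condition phase of a standardized-load protocol.  Because
    consecutive default-advance frames share 97% of their samples, the
    wavelet back-end emits on a thinned grid here (one frame every
    40.96 s); each emitted frame is computed exactly as in the default
    pipeline.  Returns, per backend, the recovered level per plateau
    (circular mean over seeds) and the median absolute error across all
    seeds and levels.
    """
    out: dict[str, dict] = {}
    for backend in backends:
        cfg = StftConfig() if backend == "stft" else CwtConfig(n_shift=4096)
        errors = []
        recovered: dict[str, float] = {}
        for li, (name, theta) in enumerate(thetas.items()):
            estimates = []
            for i in range(n_seeds):
                spec = SimulationSpec(
                    duration=duration,
                    theta=ThetaProfile(theta),
                    seed=_child_seed(seed, li, i),
                )
                series = _series(simulate_pair(spec), cfg, backend)
                _, phases = series.ungated()
                if phases.size == 0:
                    errors.append(np.pi)
                    continue
                est = circular_mean(phases)
                estimates.append(est)
                errors.append(abs(est - theta))
            recovered[name] = circular_mean(np.array(estimates)) if estimates else np.nan
        out[backend] = {
            "recovered": recovered,
            "median_abs_error": float(np.median(errors)),
            "n_seeds": n_seeds,
        }
    return out


def gating_specificity(
    seed: int = 0,
    n_frames: int = 50,
    backends: tuple[str, ...] = ("stft", "cwt"),
) -> dict[str, float]:
    """Fraction of gated samples on pairs of independent noise.

    With no shared signal the coherence gate at 0.6 should reject nearly all
    frames; one frame per seed, one emitted sample per frame.
    """
    out: dict[str, float] = {}
    for backend in backends:
        cfg = StftConfig() if backend == "stft" else CwtConfig()
        engine = StftFrameEngine(cfg) if backend == "stft" else CwtFrameEngine(cfg)
        gated = 0
        for i in range(n_frames):
            rng = np.random.default_rng(_child_seed(seed, 7, i))
            x = rng.normal(0.0, 9.0, cfg.n_frame)
            y = rng.normal(0.0, 18.0, cfg.n_frame)
            if engine.frame_sample(x, y, 0.0).gated:
                gated += 1
        out[backend] = gated / n_frames
    return out


def step_localization(
    seed: int = 0,
    n_seeds: int = 20,
    duration: float = 420.0,
    step_time: float = 230.0,
    theta_from: float = 0.98,
    theta_to: float = 1.37,
    ramp: float = 4.0,
) -> dict[str, float]:
    """Transition-midpoint error on a θ-step input, per backend.

    Series are computed with frame-center timestamps so the crossing time is
    directly comparable with the true step time.  Returns the median
    absolute localization error over seeds for each backend.
    """
    truth = ThetaProfile(
        theta_from,
        (ThetaSegment(step_time + ramp / 2, duration, theta=theta_to, ramp=ramp),),
    )
    errs: dict[str, list[float]] = {"stft": [], "cwt": []}
    for i in range(n_seeds):
        spec = SimulationSpec(duration=duration, theta=truth, seed=_child_seed(seed, 13, i))
        pair = simulate_pair(spec)
        for backend in ("stft", "cwt"):
            cfg = (
                StftConfig(timestamp="center")
                if backend == "stft"
                else CwtConfig(timestamp="center")
            )
            rep = recovery_report(_series(pair, cfg, backend), truth)
            err = rep.get("localization_error_s", np.nan)
            errs[backend].append(duration if np.isnan(err) else err)
    return {b: float(np.median(v)) for b, v in errs.items()}


def protocol_summary(seed: int = 0, backend: str = "stft") -> dict[str, float]:
    """Full standardized-load protocol: η sensitivities and coherent fraction."""
    spec = capnia_protocol(seed=_child_seed(seed, 21))
    pair = simulate_pair(spec)
    cfg = StftConfig(timestamp="center") if backend == "stft" else CwtConfig(timestamp="center")
    series = _series(pair, cfg, backend)
    hyper = sensitivity_eta(series, (170.0, 290.0), (300.0, 450.0), mode="min")
    hypo = sensitivity_eta(series, (170.0, 290.0), (600.0, 750.0), mode="max")
    return {
        "theta_bar": hyper.theta_bar,
        "eta_hypercapnia": hyper.eta,
        "eta_hypocapnia": hypo.eta,
        "coherent_fraction": coherent_fraction(series),
        "n_samples": series.n,
    }


def batch_stream_agreement(
    seed: int = 0,
    duration: float = 220.0,
    chunk_sizes: tuple[int, ...] = (1, 100, 4096),
    backends: tuple[str, ...] = ("stft", "cwt"),
) -> dict[str, float]:
    """Maximum absolute batch-vs-stream deviation over chunk sizes (exact: 0)."""
    spec = SimulationSpec(duration=duration, seed=_child_seed(seed, 31))
    pair = simulate_pair(spec)
    out: dict[str, float] = {}
    for backend in backends:
        cfg = StftConfig() if backend == "stft" else CwtConfig()
        batch = _series(pair, cfg, backend)
        worst = 0.0
        for chunk in chunk_sizes:
            stream = run_replay(pair, cfg, backend=backend, chunk_size=chunk)
            for a, b in (
                (batch.times, stream.times),
                (batch.coh_sq, stream.coh_sq),
                (batch.phase, stream.phase),
            ):
                d = np.abs(np.asarray(a) - np.asarray(b))
                d = d[~np.isnan(d)] if np.isnan(a).any() else d
                if np.isnan(a).any() and not np.array_equal(np.isnan(a), np.isnan(b)):
                    worst = np.inf
                worst = max(worst, float(d.max(initial=0.0)))
        out[backend] = worst
    return out
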