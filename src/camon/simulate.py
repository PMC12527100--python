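"""Synthetic hemodynamics: seeded BP/BFV pairs with a known Mayer-band phase shift.

The simulator emulates the component structure of bedside recordings — heart
rate waves, respiratory waves, Mayer waves (~0.1 Hz), B-waves and broadband
noise — and imposes a prescribed, possibly time-varying phase shift θ(t)
between the Mayer components of BFV and BP.  θ(t) is the ground truth the
estimators are validated against: intact autoregulation corresponds to a
baseline near +1 rad, hypercapnia (CO2 inhalation) lowers it toward ~0.45 rad
and hypocapnia (hyperventilation) raises it toward ~1.37 rad.

The model is purely phenomenological: the phase shift is imposed on the Mayer
component, not generated by a regulatory feedback mechanism.  θ enters the
instantaneous Mayer-wave argument directly, so piecewise-linear θ profiles
produce phase-continuous signals without amplitude glitches at event
boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgument
from .signals import DEFAULT_DT, SampledSignal, SignalPair

__all__ = [
    "Component",
    "ThetaSegment",
    "ThetaProfile",
    "SimulationSpec",
    "DEFAULT_COMPONENTS",
    "make_component",
    "build_theta_profile",
    "simulate_pair",
    "capnia_protocol",
]


@dataclass(frozen=True)
class Component:
    """One oscillatory constituent of the BP/BFV mixture.

    Amplitudes are given per channel (mmHg for BP, cm/s for BFV); the phase
    offset is shared, so every component except the Mayer wave is in phase
    between the two channels.
    """

    name: str
    frequency: float  # Hz
    amp_bp: float
    amp_bfv: float
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise InvalidArgument("component frequency must be >= 0")
        if self.amp_bp < 0 or self.amp_bfv < 0:
            raise InvalidArgument("component amplitudes must be >= 0")


#: Plausible resting-state defaults with well-separated spectral bands:
#: cardiac 1.1 Hz, respiratory 0.25 Hz, Mayer 0.10 Hz, B-wave 0.02 Hz.
DEFAULT_COMPONENTS: tuple[Component, ...] = (
    Component("cardiac", 1.1, 5.0, 10.0),
    Component("respiratory", 0.25, 3.0, 5.0),
    Component("mayer", 0.10, 2.0, 4.0),
    Component("bwave", 0.02, 1.0, 2.0),
)


@dataclass(frozen=True)
class ThetaSegment:
    """One plateau of the true Mayer-band phase shift.

    The profile ramps linearly from the surrounding baseline into the plateau
    over ``ramp`` seconds before ``t_start`` and back over ``ramp`` seconds
    after ``t_end``.
    """

    t_start: float
    t_end: float
    theta: float  # rad, in (-pi, pi]
    ramp: float = 0.0  # s

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidArgument("segment must have t_end > t_start")
        if self.ramp < 0:
            raise InvalidArgument("ramp must be >= 0")
        if not (-np.pi < self.theta <= np.pi):
            raise InvalidArgument("theta must lie in (-pi, pi]")


@dataclass(frozen=True)
class ThetaProfile:
    """Piecewise definition of the true phase shift of BFV relative to BP."""

    baseline: float
    segments: tuple[ThetaSegment, ...] = ()

    def __post_init__(self) -> None:
        if not (-np.pi < self.baseline <= np.pi):
            raise InvalidArgument("baseline theta must lie in (-pi, pi]")
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        for a, b in zip(segs, segs[1:]):
            if a.t_end + a.ramp > b.t_start - b.ramp:
                raise InvalidArgument(
                    "theta segments (including ramps) must not overlap"
                )
        object.__setattr__(self, "segments", segs)

    def __call__(self, t) -> np.ndarray:
        """Evaluate θ at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline)
        for seg in self.segments:
            if seg.ramp > 0:
                m = (t >= seg.t_start - seg.ramp) & (t < seg.t_start)
                frac = (t[m] - (seg.t_start - seg.ramp)) / seg.ramp
                out[m] = self.baseline + frac * (seg.theta - self.baseline)
                m = (t > seg.t_end) & (t <= seg.t_end + seg.ramp)
                frac = (t[m] - seg.t_end) / seg.ramp
                out[m] = seg.theta + frac * (self.baseline - seg.theta)
            m = (t >= seg.t_start) & (t <= seg.t_end)
            out[m] = seg.theta
        return out

    def transitions(self) -> list[tuple[float, float, float]]:
        """(midpoint time, level before, level after) of every level change."""
        out: list[tuple[float, float, float]] = []
        for seg in self.segments:
            out.append((seg.t_start - seg.ramp / 2.0, self.baseline, seg.theta))
            out.append((seg.t_end + seg.ramp / 2.0, seg.theta, self.baseline))
        return out

    def plateau_mask(self, t, margin: float = 0.0) -> np.ndarray:
        """True where θ is constant, i.e. outside every ramp ± ``margin`` s."""
        t = np.asarray(t, dtype=float)
        keep = np.ones(t.shape, dtype=bool)
        for seg in self.segments:
            keep &= ~(
                (t > seg.t_start - seg.ramp - margin) & (t < seg.t_start + margin)
            )
            keep &= ~((t > seg.t_end - margin) & (t < seg.t_end + seg.ramp + margin))
        return keep


def build_theta_profile(baseline: float, events=()) -> ThetaProfile:
    """Build a θ profile from a baseline and a list of plateau events.

    Parameters
    ----------
    baseline : float
        Resting phase shift in rad (healthy volunteers: ~0.98 rad).
    events : iterable of ThetaSegment or mapping
        Each event is a plateau ``{t_start, t_end, theta, ramp}``; typical
        plateaus are ~0.45 rad (hypercapnic test) and ~1.37 rad (hypocapnic
        test).  Events, including their ramps, must not overlap.
    """
    segs = tuple(
        ev if isinstance(ev, ThetaSegment) else ThetaSegment(**ev) for ev in events
    )
    return ThetaProfile(baseline=baseline, segments=segs)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic recording (pure function of the spec).

    Attributes
    ----------
    duration : float
        Record length in seconds.
    dt : float
        Sampling interval, 0.01 s by default.
    components : tuple of Component
        Oscillatory mixture shared (up to amplitude) by both channels.
    mayer_frequency : float
        Frequency the component named ``"mayer"`` is moved to, Hz.  Must lie
        in the Mayer band [0.05, 0.15] Hz unless ``allow_any_mayer`` is set.
    theta : ThetaProfile
        Imposed phase shift of the BFV Mayer component relative to BP.
    noise_sd_bp, noise_sd_bfv : float
        White Gaussian noise per channel.  Defaults calibrated so that the
        squared coherence at the Mayer bin is ~0.9 with default amplitudes.
    baseline_bp, baseline_bfv : float
        Constant offsets (mmHg, cm/s).
    seed : int
        Seed for all randomness; identical seeds give bit-identical output.
    bilateral : bool
        If set, also synthesize a right BFV channel with independent noise.
    """

    duration: float
    dt: float = DEFAULT_DT
    components: tuple[Component, ...] = DEFAULT_COMPONENTS
    mayer_frequency: float = 0.10
    theta: ThetaProfile = field(default_factory=lambda: ThetaProfile(0.98))
    noise_sd_bp: float = 9.0
    noise_sd_bfv: float = 18.0
    baseline_bp: float = 90.0
    baseline_bfv: float = 60.0
    seed: int = 0
    bilateral: bool = False
    allow_any_mayer: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0 or not self.dt > 0:
            raise InvalidArgument("duration and dt must be positive")
        if self.noise_sd_bp < 0 or self.noise_sd_bfv < 0:
            raise InvalidArgument("noise standard deviations must be >= 0")
        if not self.allow_any_mayer and not 0.05 <= self.mayer_frequency <= 0.15:
            raise InvalidArgument(
                "mayer_frequency outside the 0.05-0.15 Hz Mayer band "
                "(set allow_any_mayer to override)"
            )

    @property
    def n(self) -> int:
        return int(round(self.duration / self.dt))


def make_component(
    frequency: float,
    amplitude: float,
    phase: float,
    duration: float,
    dt: float = DEFAULT_DT,
) -> SampledSignal:
    """Single sinusoid ``amplitude * sin(2π f n dt + phase)`` of given duration."""
    if duration <= 0 or dt <= 0:
        raise InvalidArgument("duration and dt must be positive")
    if frequency < 0:
        raise InvalidArgument("frequency must be >= 0")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    return SampledSignal(amplitude * np.sin(2 * np.pi * frequency * t + phase), dt=dt)


def _channel(
    spec: SimulationSpec, t: np.ndarray, theta: np.ndarray, which: str
) -> np.ndarray:
    baseline = spec.baseline_bp if which == "bp" else spec.baseline_bfv
    out = np.full(t.shape, float(baseline))
    for comp in spec.components:
        f = spec.mayer_frequency if comp.name == "mayer" else comp.frequency
        arg = 2 * np.pi * f * t + comp.phase
        if which == "bp":
            out += comp.amp_bp * np.sin(arg)
        else:
            # θ(t) advances the instantaneous Mayer argument of BFV only.
            shift = theta if comp.name == "mayer" else 0.0
            out += comp.amp_bfv * np.sin(arg + shift)
    return out


def simulate_pair(spec: SimulationSpec) -> SignalPair:
    """Synthesize a BP/BFV pair with the imposed Mayer phase-shift profile.

    BP is the component mixture plus white noise; BFV shares every component
    in phase except the Mayer component, whose argument is advanced by
    θ(t).  Noise is drawn independently per channel from a generator seeded
    with ``spec.seed``, so the output is a pure function of the spec.
    """
    n = spec.n
    t = np.arange(n) * spec.dt
    theta = spec.theta(t)
    bp = _channel(spec, t, theta, "bp")
    bfv = _channel(spec, t, theta, "bfv")
    rng = np.random.default_rng(spec.seed)
    bp = bp + rng.normal(0.0, spec.noise_sd_bp, n)
    bfv_left = bfv + rng.normal(0.0, spec.noise_sd_bfv, n)
    bfv_right = None
    if spec.bilateral:
        bfv_right = SampledSignal(
            bfv + rng.normal(0.0, spec.noise_sd_bfv, n), dt=spec.dt, units="cm/s"
        )
    return SignalPair(
        bp=SampledSignal(bp, dt=spec.dt, units="mmHg"),
        bfv_left=SampledSignal(bfv_left, dt=spec.dt, units="cm/s"),
        bfv_right=bfv_right,
    )


def capnia_protocol(
    duration: float = 900.0,
    baseline: float = 0.98,
    hypercapnic: float = 0.45,
    hypocapnic: float = 1.37,
    hyper_interval: tuple[float, float] = (300.0, 450.0),
    hypo_interval: tuple[float, float] = (600.0, 750.0),
    ramp: float = 20.0,
    seed: int = 0,
    **kwargs,
) -> SimulationSpec:
    """Standardized-load scenario: baseline, a hypercapnic dip, a hypocapnic rise.

    Mirrors a CO2-inhalation test (phase shift dropping to ~0.45 rad) followed
    by a hyperventilation test (rising to ~1.37 rad) around a healthy
    ~0.98 rad baseline.
    """
    theta = build_theta_profile(
        baseline,
        [
            ThetaSegment(*hyper_interval, theta=hypercapnic, ramp=ramp),
            ThetaSegment(*hypo_interval, theta=hypocapnic, ramp=ramp),
        ],
    )
    return SimulationSpec(duration=duration, theta=theta, seed=seed, **kwargs)
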