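"""Chain-of-offsets (COOM) and task-block simulators with analytic ground truth.

The chain-of-offsets model generates every channel as an amplitude-scaled,
phase-shifted copy of one seed waveform,

    x_k(t) = a_k * phi(omega * t - alpha_k) + noise,

the signature of a traveling wave sampled at fixed sensors: a propagation
pattern U(xi, t) = a(xi) * u(omega*t - h(xi)) observed at sites xi_k reduces
to COOM with offsets alpha_k = h(xi_k) (phase units of the waveform
argument).  For a periodic seed with Fourier coefficients c_m
(phi(theta) = sum_m 2 Re(c_m e^{i m theta})) the continuous-limit lead
matrix is available in closed form, one rank-2 skew-symmetric term per
harmonic — the oracle used to validate the numeric pipeline.  The same
formalism covers solitary ripples (pulse trains with rest between events;
the length of the calm interval does not affect the oriented areas) and
two-channel task-block designs in which the leader-follower role alternates
between blocks, producing reversal-rich trajectories.

Noise is i.i.d. Gaussian per frame and channel; SNR is defined as
(signal RMS / noise sd)^2 with the RMS taken over the noiseless recording.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

from .areas import LeadMatrix
from .exceptions import SpecError
from .io import Recording

__all__ = [
    "FourierSeed",
    "PulseSeed",
    "CoomSpec",
    "coom_series",
    "WaveFieldSpec",
    "wave_series",
    "ripple_train",
    "BlockDesign",
    "block_pair",
    "social_design",
    "motor_design",
    "analytic_lead_matrix",
    "warp_time",
    "noise_sd_for_snr",
]


@dataclasses.dataclass(frozen=True)
class FourierSeed:
    """Periodic seed phi(theta) = sum_{m>=1} 2 Re(c_m exp(i m theta)).

    ``coefficients[m-1]`` is the complex exponential-convention coefficient
    c_m; phi = cos(theta) corresponds to coefficients = (0.5,).
    """

    coefficients: tuple[complex, ...]

    def __init__(self, coefficients: Sequence[complex]):
        object.__setattr__(
            self, "coefficients", tuple(complex(c) for c in coefficients)
        )
        if not self.coefficients:
            raise SpecError("at least one Fourier coefficient required")

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for m, c in enumerate(self.coefficients, start=1):
            out += 2.0 * (c * np.exp(1j * m * theta)).real
        return out


@dataclasses.dataclass(frozen=True)
class PulseSeed:
    """Gaussian bump phi(theta) = exp(-(theta/width)^2), width in phase units."""

    width: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise SpecError("pulse width must be positive")

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return np.exp(-((theta / self.width) ** 2))


@dataclasses.dataclass
class CoomSpec:
    """Chain-of-offsets specification.

    Offsets are phases in [0, 2*pi) of the seed argument; omega is the
    angular frequency (rad/s); duration and dt are in seconds.
    """

    n: int
    amplitudes: np.ndarray
    offsets: np.ndarray
    seed_function: FourierSeed | PulseSeed
    omega: float
    duration: float
    dt: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.n < 2:
            raise SpecError("need at least 2 channels")
        if self.amplitudes.shape != (self.n,) or self.offsets.shape != (self.n,):
            raise SpecError("amplitudes/offsets must have length n")
        if np.any(self.amplitudes <= 0):
            raise SpecError("amplitudes must be positive")
        if not (self.omega > 0 and self.duration > 0 and self.dt > 0):
            raise SpecError("omega, duration, dt must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if isinstance(self.seed_function, FourierSeed):
            period = 2.0 * math.pi / self.omega
            if self.duration < period:
                raise SpecError("duration must cover at least one period")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def noise_sd_for_snr(signal: np.ndarray, snr: float) -> float:
    """Noise sd giving the requested SNR = (signal RMS / noise sd)^2."""
    if snr <= 0:
        raise SpecError("snr must be positive")
    rms = float(np.sqrt(np.mean(np.square(signal))))
    return rms / math.sqrt(snr)


def _label(n: int) -> list[str]:
    return [f"ch{k + 1:02d}" for k in range(n)]


def coom_series(spec: CoomSpec) -> Recording:
    """Sample x_k(t_i) = a_k * phi(omega*t_i - alpha_k) + noise, seeded."""
    t = spec.times
    theta = spec.omega * t[None, :] - spec.offsets[:, None]
    clean = spec.amplitudes[:, None] * spec.seed_function(theta)
    rng = np.random.default_rng(spec.seed)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=clean.shape)
        if spec.noise_sd > 0
        else 0.0
    )
    return Recording(
        clean + noise, _label(spec.n), dt=spec.dt, id=f"coom-seed{spec.seed}"
    )


@dataclasses.dataclass
class WaveFieldSpec:
    """Traveling-wave field U(xi, t) = a(xi) * u(omega*t - h(xi)).

    ``positions`` are the sensor sites xi_k; ``amplitude`` and ``delay`` map a
    site to its local scale a(xi) and phase delay h(xi) (phase units of the
    waveform argument; a flat wave has linear h, a spherical wave h = distance
    from the excitation center).
    """

    positions: np.ndarray
    amplitude: Callable[[np.ndarray], np.ndarray]
    delay: Callable[[np.ndarray], np.ndarray]
    waveform: FourierSeed | PulseSeed
    omega: float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))


def wave_series(
    spec: WaveFieldSpec,
    duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Sample a traveling wave at its sensors (reduces to COOM with
    alpha_k = h(xi_k))."""
    amps = np.asarray([float(spec.amplitude(xi)) for xi in spec.positions])
    offs = np.asarray([float(spec.delay(xi)) for xi in spec.positions])
    coom = CoomSpec(
        n=spec.positions.shape[0],
        amplitudes=amps,
        offsets=offs,
        seed_function=spec.waveform,
        omega=spec.omega,
        duration=duration,
        dt=dt,
        noise_sd=noise_sd,
        seed=seed,
    )
    rec = coom_series(coom)
    rec.id = f"wave-seed{seed}"
    return rec


def ripple_train(
    spec: CoomSpec, event_times: Sequence[float], rest_value: float = 0.0
) -> Recording:
    """Solitary ripples: each event emits the lagged pulse across channels.

    Channel k receives the pulse of event e_j centered at e_j + alpha_k/omega;
    channels sit at ``rest_value`` between events.  Events must be separated
    by more than the pulse extent plus the lag spread, else they overlap.
    """
    if not isinstance(spec.seed_function, PulseSeed):
        raise SpecError("ripple_train requires a pulse-type seed function")
    events = np.sort(np.asarray(event_times, dtype=float))
    lag_times = spec.offsets / spec.omega
    extent = 8.0 * spec.seed_function.width / spec.omega
    min_sep = extent + (lag_times.max() - lag_times.min())
    if events.size > 1 and np.any(np.diff(events) <= min_sep):
        raise SpecError(
            f"events overlap: separation must exceed {min_sep:.3g} s"
        )
    t = spec.times
    clean = np.full((spec.n, t.size), float(rest_value))
    for e in events:
        theta = spec.omega * (t[None, :] - e) - spec.offsets[:, None]
        clean += spec.amplitudes[:, None] * spec.seed_function(theta)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return Recording(clean, _label(spec.n), dt=spec.dt, id=f"ripples-seed{spec.seed}")


@dataclasses.dataclass
class BlockDesign:
    """Two-channel task-block design.

    ``bounds`` are the block boundaries in seconds (len = n_blocks + 1,
    starting at 0, strictly increasing); ``signs[b]`` is +1 when channel 1
    leads during block b, -1 when channel 2 leads, 0 for a rest block with no
    pulses; ``lag`` is the lag magnitude in seconds.
    """

    bounds: np.ndarray
    signs: np.ndarray
    lag: float

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        self.signs = np.asarray(self.signs, dtype=int)
        if self.bounds.ndim != 1 or self.bounds.size != self.signs.size + 1:
            raise SpecError("need len(bounds) == len(signs) + 1")
        if np.any(np.diff(self.bounds) <= 0):
            raise SpecError("block boundaries must be strictly increasing")
        if not (self.lag > 0):
            raise SpecError("lag must be positive")

    @property
    def duration(self) -> float:
        return float(self.bounds[-1])


def social_design(
    duration: float = 1200 * 0.72, segment: float = 38.0, lag: float = 2 * 0.72
) -> BlockDesign:
    """Leader alternating at every social-task segment boundary (38 s)."""
    n_blocks = int(math.ceil(duration / segment))
    bounds = np.minimum(np.arange(n_blocks + 1) * segment, duration)
    signs = np.array([1 if b % 2 == 0 else -1 for b in range(n_blocks)])
    return BlockDesign(bounds=bounds, signs=signs, lag=lag)


def motor_design(lag: float = 2 * 0.72) -> BlockDesign:
    """HCP-style motor run: 13 contiguous 15-s blocks.

    Ten movement blocks (3-s cue + 12-s movement) and three 15-s fixation
    blocks; the leader-follower role alternates at every block boundary,
    giving 12 interior reversals over the 195-s run.
    """
    bounds = np.arange(14) * 15.0
    signs = np.array([1 if b % 2 == 0 else -1 for b in range(13)])
    return BlockDesign(bounds=bounds, signs=signs, lag=lag)


def block_pair(
    design: BlockDesign,
    pulse_rate: float = 0.25,
    dt: float = 0.72,
    noise_sd: float = 0.0,
    seed: int = 0,
    pulse_width: float = 1.0,
    snr: float | None = None,
) -> Recording:
    """Two-channel pulse recording whose lead-lag sign follows the design.

    Channel 1 is a regular pulse train (``pulse_rate`` pulses per second in
    non-rest blocks); channel 2 is its copy lagged by +lag in +1 blocks and
    -lag in -1 blocks, so the oriented-area trajectory a_12(t) rises in +1
    blocks and falls in -1 blocks, with persistent extrema at block
    boundaries.  If ``snr`` is given it overrides ``noise_sd`` via
    ``noise_sd_for_snr`` on the noiseless pair.
    """
    if pulse_rate <= 0:
        raise SpecError("pulse_rate must be positive")
    spacing = 1.0 / pulse_rate
    if design.lag >= spacing:
        raise SpecError(
            f"lag {design.lag} s must be smaller than pulse spacing {spacing} s"
        )
    T = int(round(design.duration / dt))
    t = np.arange(T) * dt
    x1 = np.zeros(T)
    x2 = np.zeros(T)
    for b, sign in enumerate(design.signs):
        if sign == 0:
            continue
        lo, hi = design.bounds[b], design.bounds[b + 1]
        n_pulses = int((hi - lo) * pulse_rate)
        centers = lo + (np.arange(n_pulses) + 0.5) * spacing
        centers = centers[centers + abs(design.lag) < hi]
        for c in centers:
            x1 += np.exp(-(((t - c) / pulse_width) ** 2))
            x2 += np.exp(-(((t - c - sign * design.lag) / pulse_width) ** 2))
    clean = np.vstack([x1, x2])
    sd = noise_sd_for_snr(clean, snr) if snr is not None else noise_sd
    rng = np.random.default_rng(seed)
    values = clean + (rng.normal(0.0, sd, size=clean.shape) if sd > 0 else 0.0)
    return Recording(values, ["lead", "follow"], dt=dt, id=f"blocks-seed{seed}")


def analytic_lead_matrix(spec: CoomSpec) -> LeadMatrix:
    """Continuous-limit lead matrix of a noiseless Fourier-seed COOM.

    One rank-2 skew-symmetric term per harmonic:

        a_kl = (duration / period) * 4*pi * a_k * a_l
               * sum_m m * |c_m|^2 * sin(m * (alpha_l - alpha_k)).

    The overall constant and sign were fixed against direct quadrature of the
    continuous oriented-area integral on one dense period (positive a_kl
    means channel k leads, i.e. alpha_l > alpha_k for small shifts); they
    depend on the exponential Fourier convention of ``FourierSeed``.
    """
    if not isinstance(spec.seed_function, FourierSeed):
        raise SpecError("analytic lead matrix requires a Fourier-type seed")
    if spec.noise_sd != 0:
        raise SpecError("analytic lead matrix is defined for noiseless specs")
    coeffs = spec.seed_function.coefficients
    dalpha = spec.offsets[None, :] - spec.offsets[:, None]  # alpha_l - alpha_k
    A = np.zeros((spec.n, spec.n))
    for m, c in enumerate(coeffs, start=1):
        A += m * abs(c) ** 2 * np.sin(m * dalpha)
    A *= 4.0 * math.pi * np.outer(spec.amplitudes, spec.amplitudes)
    A *= spec.duration / spec.period
    return LeadMatrix(entries=A, channel_labels=_label(spec.n))


def warp_time(rec: Recording, warp: Callable[[np.ndarray], np.ndarray]) -> Recording:
    """Resample a recording along a monotone reparametrization of its timeline.

    ``warp`` must map [0, span] onto itself strictly increasingly with fixed
    endpoints; each channel's linear interpolation is resampled at the warped
    frame times, preserving T.
    """
    t = np.arange(rec.n_frames) * rec.dt
    tw = np.asarray(warp(t), dtype=float)
    if np.any(np.diff(tw) <= 0):
        raise SpecError("warp must be strictly increasing")
    if not (
        math.isclose(tw[0], t[0], abs_tol=1e-9)
        and math.isclose(tw[-1], t[-1], rel_tol=1e-9, abs_tol=1e-9)
    ):
        raise SpecError("warp must fix the endpoints of the timeline")
    values = np.vstack([np.interp(tw, t, ch) for ch in rec.values])
    return Recording(values, list(rec.channel_labels), dt=rec.dt, id=rec.id + "-warped")
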