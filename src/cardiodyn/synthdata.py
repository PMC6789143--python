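"""Synthetic inputs with known ground truth.

Everything downstream is validated against these generators: twin-peak
contraction waveforms (with optional arrhythmia-like aberrations),
fractional Brownian motion with exact covariance (circulant embedding),
a Lorenz trajectory as a chaotic reference, and rendered textured videos
whose per-frame displacement field is known exactly.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import InvalidInputError, InvalidSpecError
from .motiontrack import FrameSequence, MotionWaveform

__all__ = [
    "BeatSimSpec",
    "GroundTruthPeaks",
    "simulate_waveform",
    "simulate_fbm",
    "simulate_lorenz",
    "render_video",
    "simulate_beat_video",
]


@dataclass
class BeatSimSpec:
    """Parameters of a simulated contraction-motion waveform.

    Each beat is a Gaussian contraction pulse followed by a Gaussian
    relaxation pulse offset by ``relax_offset_frac`` of the beat period.
    ``peak_width_s`` is the Gaussian sigma. Aberrations are phenomenological:
    whole-beat deletions, spurious spikes, and multiplicative amplitude
    jitter.
    """

    bpm: float = 60.0
    duration_s: float = 20.0
    fps: float = 100.0
    contraction_amp: float = 20.0  # µm/s
    relaxation_amp: float = 15.0  # µm/s
    peak_width_s: float = 0.03
    relax_offset_frac: float = 0.3
    noise_sd: float = 0.0
    missed_beat_prob: float = 0.0
    spike_prob: float = 0.0
    amp_jitter_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bpm <= 0 or self.fps <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("bpm, fps and duration_s must be positive")
        if self.contraction_amp <= 0 or self.relaxation_amp <= 0:
            raise InvalidSpecError("pulse amplitudes must be positive")
        for p in (self.missed_beat_prob, self.spike_prob):
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError("probabilities must lie in [0, 1]")
        period = 60.0 / self.bpm
        if self.duration_s < 2 * period:
            raise InvalidSpecError("duration must cover at least 2 beats")
        if not 0.0 < self.relax_offset_frac < 1.0:
            raise InvalidSpecError("relax_offset_frac must be in (0, 1)")
        gap = period * min(self.relax_offset_frac, 1.0 - self.relax_offset_frac)
        if 4.0 * self.peak_width_s > gap:
            raise InvalidSpecError(
                f"peak_width_s={self.peak_width_s} too large for bpm={self.bpm}: "
                "contraction and relaxation pulses would overlap"
            )

    @property
    def period_s(self) -> float:
        return 60.0 / self.bpm


@dataclass
class GroundTruthPeaks:
    """Exact peak times/amplitudes used by the simulator."""

    contraction: list[tuple[float, float]] = field(default_factory=list)
    relaxation: list[tuple[float, float]] = field(default_factory=list)
    missed_beats: list[int] = field(default_factory=list)
    spikes: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.contraction)


def _pulse(t: np.ndarray, center: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_waveform(spec: BeatSimSpec) -> tuple[MotionWaveform, GroundTruthPeaks]:
    """Simulate a twin-peak contraction waveform.

    Beat i places its contraction pulse at (i + 0.2) * period and its
    relaxation pulse ``relax_offset_frac`` of a period later, so that for
    round rates every pulse center falls on the sample grid. Returns the
    waveform and the exact peak bookkeeping.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    S = np.zeros(n)
    period = spec.period_s
    sigma = spec.peak_width_s
    truth = GroundTruthPeaks()
    n_beats = int(np.floor(spec.duration_s / period + 1e-9))
    for i in range(n_beats):
        c_center = (i + 0.2) * period
        r_center = c_center + spec.relax_offset_frac * period
        if r_center + 4 * sigma > spec.duration_s:
            break
        if rng.random() < spec.missed_beat_prob:
            truth.missed_beats.append(i)
            continue
        c_amp, r_amp = spec.contraction_amp, spec.relaxation_amp
        if spec.amp_jitter_frac > 0:
            c_amp *= max(0.05, 1.0 + spec.amp_jitter_frac * rng.standard_normal())
            r_amp *= max(0.05, 1.0 + spec.amp_jitter_frac * rng.standard_normal())
        S += _pulse(t, c_center, c_amp, sigma)
        S += _pulse(t, r_center, r_amp, sigma)
        truth.contraction.append((c_center, c_amp))
        truth.relaxation.append((r_center, r_amp))
        if rng.random() < spec.spike_prob:
            s_center = (i + rng.uniform(0.55, 0.95)) * period
            s_amp = 1.5 * spec.contraction_amp
            S += _pulse(t, s_center, s_amp, sigma / 2.0)
            truth.spikes.append((s_center, s_amp))
    if spec.noise_sd > 0:
        S += rng.normal(0.0, spec.noise_sd, n)
        np.clip(S, 0.0, None, out=S)  # tracked speeds are non-negative
    w = MotionWaveform(t=t, S=S, fps=spec.fps, meta={"source": "simulate_waveform", **asdict(spec)})
    return w, truth


def simulate_fbm(H: float, n: int, seed: int = 0) -> np.ndarray:
    """Fractional Brownian motion by circulant embedding (Davies-Harte).

    Generates fractional Gaussian noise with the exact target covariance
    rho(k) = ((k+1)^2H - 2 k^2H + |k-1|^2H) / 2, then cumulatively sums.
    Increment variance is exactly 1.
    """
    if not 0.0 < H < 1.0:
        raise InvalidInputError(f"Hurst exponent must be in (0, 1), got {H}")
    if n < 256:
        raise InvalidInputError(f"need n >= 256, got {n}")
    rng = np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    rho = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([rho, rho[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # tiny negative round-off eigenvalues
    m = 2 * n
    g = rng.standard_normal(m)
    h = rng.standard_normal(m)
    V = np.empty(m, dtype=complex)
    V[0] = np.sqrt(lam[0]) * g[0]
    V[n] = np.sqrt(lam[n]) * g[n]
    j = np.arange(1, n)
    V[j] = np.sqrt(lam[j] / 2.0) * (g[j] + 1j * h[j])
    V[m - j] = np.conj(V[j])
    fgn = np.fft.fft(V).real[:n] / np.sqrt(m)
    return np.cumsum(fgn)


_LORENZ_SIGMA, _LORENZ_RHO, _LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0


def _lorenz_rhs(s: np.ndarray) -> np.ndarray:
    x, y, z = s
    return np.array(
        [
            _LORENZ_SIGMA * (y - x),
            x * (_LORENZ_RHO - z) - y,
            x * y - _LORENZ_BETA * z,
        ]
    )


def simulate_lorenz(
    n: int, dt: float = 0.01, seed_state: int = 0, transient: int = 1000
) -> np.ndarray:
    """x-coordinate of a Lorenz trajectory (sigma=10, rho=28, beta=8/3).

    Fixed-step 4th-order Runge-Kutta; ``transient`` initial steps are
    discarded. The initial condition is jittered deterministically from
    ``seed_state``.
    """
    if n < 5000:
        raise InvalidInputError(f"need n >= 5000, got {n}")
    if not 0.005 <= dt <= 0.05:
        raise InvalidInputError(f"dt must be in [0.005, 0.05], got {dt}")
    rng = np.random.default_rng(seed_state)
    s = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
    out = np.empty(n)
    total = transient + n
    for i in range(total):
        k1 = _lorenz_rhs(s)
        k2 = _lorenz_rhs(s + 0.5 * dt * k1)
        k3 = _lorenz_rhs(s + 0.5 * dt * k2)
        k4 = _lorenz_rhs(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= transient:
            out[i - transient] = s[0]
    return out


def _make_texture(shape: tuple[int, int], seed: int, corr_px: float = 4.0) -> np.ndarray:
    """Band-limited periodic noise texture; blocks are uniquely matchable."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(shape)
    tex = gaussian_filter(raw, sigma=corr_px / 2.0, mode="wrap")
    tex -= tex.min()
    tex /= tex.max()
    return tex * 255.0


def render_video(
    w,
    texture_seed: int = 0,
    frame_shape: tuple[int, int] = (96, 96),
    fps: float | None = None,
    um_per_px: float = 1.0,
) -> tuple[FrameSequence, np.ndarray]:
    """Render a textured video undergoing a known global translation.

    ``w`` is either a :class:`MotionWaveform` (its speed becomes a per-frame
    x-displacement ``S/(um_per_px * fps)``) or an array of per-frame-pair
    (dy, dx) pixel displacements, shape (n_frames - 1, 2). The texture is
    periodic, so integer shifts are exact everywhere. Returns the frame
    sequence and the ground-truth per-frame-pair displacement fields.
    """
    if frame_shape[0] < 64 or frame_shape[1] < 64:
        raise InvalidInputError(f"frame_shape must be at least 64x64, got {frame_shape}")
    if isinstance(w, MotionWaveform):
        fps = w.fps
        steps_x = w.S[1:] / (um_per_px * fps)
        schedule = np.column_stack([np.zeros_like(steps_x), steps_x])
    else:
        schedule = np.asarray(w, dtype=float)
        if schedule.ndim != 2 or schedule.shape[1] != 2:
            raise InvalidInputError("displacement schedule must have shape (n-1, 2)")
        if fps is None:
            fps = 100.0
    positions = np.vstack([[0.0, 0.0], np.cumsum(schedule, axis=0)])
    limit = min(frame_shape) / 4.0
    if np.max(np.abs(positions)) > limit:
        raise InvalidInputError(
            f"cumulative displacement {np.max(np.abs(positions)):.1f} px exceeds "
            f"frame_shape/4 = {limit:.1f} px"
        )
    tex = _make_texture(frame_shape, texture_seed)
    yy, xx = np.mgrid[0 : frame_shape[0], 0 : frame_shape[1]].astype(float)
    frames = np.empty((len(positions),) + tuple(frame_shape))
    for k, (py, px) in enumerate(positions):
        # content moves by +p, so frame k samples the texture at x - p
        frames[k] = map_coordinates(tex, [yy - py, xx - px], order=1, mode="grid-wrap")
    seq = FrameSequence(frames=frames, fps=fps, um_per_px=um_per_px)
    return seq, schedule


def simulate_beat_video(
    spec: BeatSimSpec,
    texture_seed: int = 0,
    frame_shape: tuple[int, int] = (96, 96),
    um_per_px: float = 1.0,
) -> tuple[FrameSequence, MotionWaveform, GroundTruthPeaks]:
    """Render a video of a texture driven by a beat-like velocity.

    The contraction stroke displaces the texture in +x, the relaxation
    stroke in -x (keeping the net drift small), so the tracked speed
    waveform should match ``|v|`` — returned as the ground-truth waveform
    alongside the exact peak list.
    """
    w, truth = simulate_waveform(spec)
    t = w.t
    v = np.zeros_like(t)
    sigma = spec.peak_width_s
    for (tc, ac), (tr, ar) in zip(truth.contraction, truth.relaxation):
        v += _pulse(t, tc, ac, sigma)
        v -= _pulse(t, tr, ar, sigma)
    for ts, amp in truth.spikes:
        v += _pulse(t, ts, amp, sigma / 2.0)
    speed = np.abs(v)
    truth_wave = MotionWaveform(
        t=t, S=speed, fps=spec.fps, meta={"source": "simulate_beat_video", **asdict(spec)}
    )
    steps_x = v[1:] / (um_per_px * spec.fps)
    schedule = np.column_stack([np.zeros_like(steps_x), steps_x])
    seq, _ = render_video(
        schedule,
        texture_seed=texture_seed,
        frame_shape=frame_shape,
        fps=spec.fps,
        um_per_px=um_per_px,
    )
    return seq, truth_wave, truth
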