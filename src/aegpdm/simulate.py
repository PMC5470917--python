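"""Synthetic two-unit inertial sensor streams for gait modelling and fall
detection.

The generator emulates the statistical structure the model assumes rather
than a biomechanical gait: a planar latent limit cycle

    z(t) = r(t) * (cos theta(t), sin theta(t)),
    theta(t) = 2 pi f t + phase jitter,   r(t) = radius + AR(1) jitter,

drives the 12 raw sensor axes through a fixed 12 x 2 loading matrix with
per-axis amplitudes and phase offsets, on top of a 1 g gravity baseline on
the vertical accelerometer axes; i.i.d. Gaussian noise is added to the raw
axes only, and the two magnitude channels per unit are *computed* from the
noisy axes exactly as for real data.  Falls are modelled as a directional
acceleration/gyro transient at onset followed by a decay of the gait
oscillation and a rotation of the gravity baseline to a lying-like axis;
static postures carry the gravity baseline plus low-frequency sway.

Units: accelerations in g (gravity baseline 1.0), angular velocities in
rad/s; default sampling rate 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSeries, assemble_series

__all__ = [
    "WalkSimConfig",
    "FallSimConfig",
    "SimulatedDataset",
    "default_loading",
    "simulate_walk",
    "simulate_fall",
    "simulate_posture",
]

#: Raw-axis indices: (u1) ax ay az wx wy wz, (u2) ax ay az wx wy wz.
_GRAVITY_AXES = (2, 8)                       # az of each unit, upright
_LATERAL_AXES = (0, 6)                       # ax of each unit
_LONGITUDINAL_AXES = (1, 7)                  # ay of each unit
_LATERAL_GYRO = (4, 10)                      # wy
_LONGITUDINAL_GYRO = (3, 9)                  # wx

_FALL_AXES = {
    "left": (_LATERAL_AXES, _LATERAL_GYRO, +1.0),
    "right": (_LATERAL_AXES, _LATERAL_GYRO, -1.0),
    "forward": (_LONGITUDINAL_AXES, _LONGITUDINAL_GYRO, +1.0),
    "backward": (_LONGITUDINAL_AXES, _LONGITUDINAL_GYRO, -1.0),
}


def default_loading() -> np.ndarray:
    """Default 12 x 2 loading: per-axis amplitude and phase offset.

    Amplitudes are a fixed spread (0.3-0.9 g for accelerometer axes,
    0.3-0.9 rad/s for gyro axes) and phases are spread over the cycle so
    no two axes are colinear functions of the latent phase.
    """
    amps = np.array([0.9, 0.7, 0.5, 0.6, 0.8, 0.4,
                     0.5, 0.9, 0.6, 0.7, 0.3, 0.8])
    phases = 2.0 * np.pi * np.arange(12) / 12.0 + 0.2
    return amps[:, None] * np.column_stack([np.cos(phases), np.sin(phases)])


@dataclass
class WalkSimConfig:
    """Quasi-periodic gait at a configurable cadence.

    ``phase_jitter_sd`` (rad/frame) and ``radius_jitter_sd`` perturb the
    latent cycle so it is quasi-periodic rather than exactly harmonic.
    """

    gait_freq: float = 1.0          # Hz
    rate: float = 10.0              # Hz
    duration: float = 10.0          # s
    latent_radius: float = 1.0
    loading: np.ndarray | None = None
    noise_sd: float = 0.05          # raw-axis observation noise (g, rad/s)
    phase_jitter_sd: float = 0.02
    radius_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0 or self.gait_freq <= 0:
            raise ValueError("rates and durations must be positive")
        if self.loading is not None:
            self.loading = np.asarray(self.loading, dtype=float)
            if self.loading.shape != (12, 2) or not np.all(np.isfinite(self.loading)):
                raise ValueError("loading must be a finite (12, 2) matrix")


@dataclass
class FallSimConfig:
    """A directional fall transient injected into a walking sequence."""

    direction: str = "forward"
    onset_time: float = 8.0         # s
    amplitude: float = 3.0          # g, peak of the acceleration transient
    decay: float = 0.5              # s, post-onset decay constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in _FALL_AXES:
            raise ValueError(
                f"direction must be one of {sorted(_FALL_AXES)}, "
                f"got {self.direction!r}"
            )
        if self.amplitude <= 0:
            raise ValueError("transient amplitude must be positive")


@dataclass
class SimulatedDataset:
    """A generated sequence plus its ground truth."""

    series: FeatureSeries
    latent: np.ndarray              # (N, 2) true latent path
    labels: np.ndarray              # (N,) in {walk, stand, lie, fall}
    raw: np.ndarray                 # (N, 12) raw axes as written to CSV
    t: np.ndarray                   # (N,) timestamps in seconds
    onset: int | None = None


def _walk_raw(config: WalkSimConfig):
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.rate))
    t = np.arange(n) / config.rate
    theta = 2.0 * np.pi * config.gait_freq * t + np.cumsum(
        rng.normal(0.0, config.phase_jitter_sd, n)
    )
    eta = np.empty(n)
    eta[0] = 0.0
    shocks = rng.normal(0.0, config.radius_jitter_sd, n)
    for i in range(1, n):
        eta[i] = 0.9 * eta[i - 1] + shocks[i]
    z = (config.latent_radius + eta)[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    loading = config.loading if config.loading is not None else default_loading()
    raw = z @ loading.T + rng.normal(0.0, config.noise_sd, (n, 12))
    for a in _GRAVITY_AXES:
        raw[:, a] += 1.0
    return t, z, raw


def simulate_walk(config: WalkSimConfig | None = None) -> SimulatedDataset:
    """Generate a quasi-periodic walking sequence; pure function of config."""
    config = config or WalkSimConfig()
    t, z, raw = _walk_raw(config)
    return SimulatedDataset(
        series=assemble_series(raw, rate=config.rate, t=t),
        latent=z,
        labels=np.full(len(t), "walk", dtype=object),
        raw=raw,
        t=t,
    )


def simulate_fall(walk: WalkSimConfig | None = None,
                  fall: FallSimConfig | None = None) -> SimulatedDataset:
    """Walking that transitions into a directional fall.

    Frames before onset are identical to :func:`simulate_walk` with the
    same walking config (same seed, same noise draws).  From onset, the
    gait oscillation decays, a direction-signed acceleration and angular
    velocity transient is injected, and the gravity baseline rotates from
    the upright axis to the direction's lying-like axis.
    """
    walk = walk or WalkSimConfig()
    fall = fall or FallSimConfig()
    if not (0.0 <= fall.onset_time < walk.duration):
        raise ValueError("fall onset must lie inside the sequence duration")
    t, z, raw = _walk_raw(walk)
    i0 = int(round(fall.onset_time * walk.rate))
    acc_axes, gyro_axes, sign = _FALL_AXES[fall.direction]

    tau = np.maximum(t[i0:] - t[i0], 0.0)
    fade = np.exp(-tau / fall.decay)         # gait + upright gravity decay
    loading = walk.loading if walk.loading is not None else default_loading()
    gait = z @ loading.T
    raw[i0:] -= gait[i0:] * (1.0 - fade)[:, None]
    for a in _GRAVITY_AXES:
        raw[i0:, a] -= (1.0 - fade)          # upright gravity fades out
    for a in acc_axes:
        raw[i0:, a] += sign * (fall.amplitude * fade + (1.0 - fade))
    for a in gyro_axes:
        raw[i0:, a] += sign * 2.0 * fall.amplitude * tau / fall.decay * fade

    labels = np.full(len(t), "walk", dtype=object)
    labels[i0:] = "fall"
    latent = z.copy()
    return SimulatedDataset(
        series=assemble_series(raw, rate=walk.rate, t=t),
        latent=latent,
        labels=labels,
        raw=raw,
        t=t,
        onset=i0,
    )


def simulate_posture(kind: str, duration: float = 10.0, rate: float = 10.0,
                     sway_sd: float = 0.05, seed: int = 0) -> SimulatedDataset:
    """A static posture (``"stand"`` or ``"lie"``) with low-frequency sway.

    Standing carries the 1 g baseline on the upright (az) axes, lying on
    the longitudinal (ay) axes.  Sway is a slow (0.15 Hz) sinusoid with
    seeded per-axis phases plus a touch of slow filtered noise; there is no
    periodic gait component, so spectral power stays below 0.5 Hz.
    """
    if kind not in ("stand", "lie"):
        raise ValueError(f"kind must be 'stand' or 'lie', got {kind!r}")
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    raw = np.zeros((n, 12))
    if sway_sd > 0:
        phases = rng.uniform(0.0, 2.0 * np.pi, 12)
        sway = sway_sd * np.sin(2.0 * np.pi * 0.15 * t[:, None] + phases)
        slow = rng.normal(0.0, sway_sd, (n, 12))
        for i in range(1, n):                # one-pole low-pass, ~0.2 Hz
            slow[i] = 0.88 * slow[i - 1] + 0.12 * slow[i]
        raw = sway + 0.5 * slow
    axes = _GRAVITY_AXES if kind == "stand" else _LONGITUDINAL_AXES
    for a in axes:
        raw[:, a] += 1.0
    return SimulatedDataset(
        series=assemble_series(raw, rate=rate, t=t),
        latent=np.zeros((n, 2)),
        labels=np.full(n, kind, dtype=object),
        raw=raw,
        t=t,
    )
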