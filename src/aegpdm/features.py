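"""Observation-vector assembly and normalization for two-unit inertial sensors.

A walking subject carries two sensor units (one in a trouser pocket, one on
the wrist), each reporting tri-axial acceleration and tri-axial angular
velocity.  Per frame the raw 12 axes are augmented with the Euclidean
magnitude of each triad, giving the fixed 16-channel observation vector

    (Ax, Ay, Az, AT, wx, wy, wz, wT)  for unit 1, then unit 2,

where ``AT = sqrt(Ax^2 + Ay^2 + Az^2)`` and ``wT`` likewise for the gyro.
The magnitude channels add a measure of movement intensity that is robust
to device orientation.  Channels are Z-scored per training set before
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column order of the raw 12 axes in a sensor frame (and in the CSV dialect).
RAW_AXES = tuple(
    f"u{u}_{c}" for u in (1, 2) for c in ("ax", "ay", "az", "wx", "wy", "wz")
)

#: Column order of the assembled 16 feature channels.
FEATURE_NAMES = tuple(
    f"u{u}_{c}" for u in (1, 2) for c in ("ax", "ay", "az", "aT", "wx", "wy", "wz", "wT")
)

N_FEATURES = 16

#: Channels below this standard deviation are treated as constant.
_SD_FLOOR = 1e-12


@dataclass
class SensorFrame:
    """One time-stamped reading from both sensor units.

    ``unit1`` and ``unit2`` each hold six values ``(ax, ay, az, wx, wy, wz)``:
    acceleration in g and angular velocity in rad/s.
    """

    t: float
    unit1: np.ndarray
    unit2: np.ndarray

    def __post_init__(self) -> None:
        self.unit1 = np.asarray(self.unit1, dtype=float)
        self.unit2 = np.asarray(self.unit2, dtype=float)
        for name, u in (("unit1", self.unit1), ("unit2", self.unit2)):
            if u.shape != (6,):
                raise ValueError(f"{name} must hold 6 channels, got shape {u.shape}")
            if not np.all(np.isfinite(u)):
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class FeatureSeries:
    """A time-ordered matrix of assembled 16-channel observations."""

    values: np.ndarray          # (N, 16)
    rate: float = 10.0          # sampling rate in Hz
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"FeatureSeries expects an (N, {N_FEATURES}) matrix, "
                f"got shape {self.values.shape}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizationStats:
    """Per-channel mean and (population) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")


def _assemble_unit(u: np.ndarray) -> np.ndarray:
    acc, gyro = u[:3], u[3:]
    return np.concatenate(
        [acc, [np.linalg.norm(acc)], gyro, [np.linalg.norm(gyro)]]
    )


def assemble_features(frame: SensorFrame) -> np.ndarray:
    """Assemble the 16-channel observation vector from one two-unit frame.

    Returns the channels in :data:`FEATURE_NAMES` order; the two magnitude
    channels per unit are the Euclidean norms of the corresponding triads.
    """
    return np.concatenate([_assemble_unit(frame.unit1), _assemble_unit(frame.unit2)])


def assemble_series(
    raw: np.ndarray, rate: float = 10.0, t: np.ndarray | None = None
) -> FeatureSeries:
    """Assemble a FeatureSeries from an (N, 12) matrix of raw axes.

    Vectorized equivalent of calling :func:`assemble_features` per row.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 12:
        raise ValueError(f"expected an (N, 12) raw-axis matrix, got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw axes contain non-finite values")
    cols = []
    for u in (0, 6):
        acc = raw[:, u : u + 3]
        gyro = raw[:, u + 3 : u + 6]
        cols += [acc, np.linalg.norm(acc, axis=1, keepdims=True),
                 gyro, np.linalg.norm(gyro, axis=1, keepdims=True)]
    return FeatureSeries(np.hstack(cols), rate=rate)


def zscore(
    series: FeatureSeries, stats: NormalizationStats | None = None
) -> tuple[FeatureSeries, NormalizationStats]:
    """Z-score a series per channel; returns the series and the stats used.

    When ``stats`` is omitted they are computed from ``series`` with the
    population (divide-by-N) standard deviation, so the output then has mean
    0 and variance 1 per channel exactly.  Supplying ``stats`` applies
    training-set statistics to held-out data.  Channels whose sd falls below
    1e-12 are mapped to zeros rather than amplified.
    """
    Y = series.values
    if stats is None:
        if len(series) < 2:
            raise ValueError("need at least 2 frames to estimate statistics")
        stats = NormalizationStats(Y.mean(axis=0), Y.std(axis=0))
    sd = np.where(stats.sd < _SD_FLOOR, 1.0, stats.sd)
    Z = (Y - stats.mean) / sd
    Z[:, stats.sd < _SD_FLOOR] = 0.0
    return FeatureSeries(Z, rate=series.rate, normalized=True), stats
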