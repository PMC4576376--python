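"""Attitude and compass heading from accelerometer + magnetometer channels.

The raw acceleration signal is split into a static part (the windowed moving
average, dominated by gravity) and a dynamic part (the residual, dominated
by locomotion).  Pitch and roll follow from the static vector with the
standard accelerometer-tilt equations; the magnetometer vector is then
rotated level with the earth's surface (tilt compensation) and the compass
heading derived from its horizontal components, with the local declination
added to convert magnetic to geographic north.

Conventions (documented, internally consistent):

* the accelerometer reads ``(0, 0, +1) g`` when the device is level;
* ``pitch = atan2(-sx, hypot(sy, sz))`` in [-90, 90] degrees (nose-up
  positive), ``roll = atan2(sy, sz)`` in (-180, 180] degrees;
* heading ``H = atan2(m_y, -m_x)`` mapped to [0, 360), i.e. a level device
  pointing magnetic north reads ``(m_x, m_y) = (-1, 0)`` up to scale — the
  two-argument arctangent resolves all four quadrants of the ratio
  ``m_y / -m_x`` that defines the compass heading;
* angles are degrees at every interface, radians internally.

Sensor frames on tags are rarely aligned with each other or with the animal,
so an :class:`AxisMap` (signed axis permutations for the magnetometer-to-
accelerometer alignment and for the mounting orientation) is applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SensorTable

__all__ = [
    "AxisMap",
    "apply_axis_map",
    "static_acceleration",
    "pitch_roll",
    "tilt_compensate",
    "heading",
]

#: fraction of the total field below which the horizontal component is
#: treated as vanishing and the heading as undefined (gimbal lock guard)
_HORIZONTAL_EPS = 1e-9


def _check_signed_permutation(M: np.ndarray, what: str) -> np.ndarray:
    M = np.asarray(M, dtype=float).reshape(3, 3)
    ok = np.all(np.isin(M, (-1.0, 0.0, 1.0)))
    A = np.abs(M)
    ok = ok and np.all(A.sum(axis=0) == 1) and np.all(A.sum(axis=1) == 1)
    if not ok:
        raise ValueError(f"{what} must be a signed permutation matrix (entries in {{-1,0,1}})")
    return M


@dataclass(frozen=True)
class AxisMap:
    """Signed-permutation transforms aligning sensor frames.

    ``mag_to_accel`` maps magnetometer axes into the accelerometer frame;
    ``mounting`` corrects the discrete orientation of the device on the
    animal and is applied to both sensors.
    """

    mag_to_accel: np.ndarray = field(default_factory=lambda: np.eye(3))
    mounting: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "mag_to_accel", _check_signed_permutation(self.mag_to_accel, "mag_to_accel"))
        object.__setattr__(self, "mounting", _check_signed_permutation(self.mounting, "mounting"))

    @property
    def accel_matrix(self) -> np.ndarray:
        return self.mounting

    @property
    def mag_matrix(self) -> np.ndarray:
        return self.mounting @ self.mag_to_accel

    def inverse(self) -> "AxisMap":
        # signed permutations are orthogonal: inverse == transpose; the
        # inverse mag_to_accel must satisfy (M m)^T (M a)... unwind order
        mount_inv = self.mounting.T
        return AxisMap(mag_to_accel=self.mag_to_accel.T, mounting=mount_inv)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# axis map: mag_to_accel rows, then mounting rows (9 signed ints each)\n")
            fh.write("mag_to_accel: " + " ".join(str(int(v)) for v in self.mag_to_accel.ravel()) + "\n")
            fh.write("mounting: " + " ".join(str(int(v)) for v in self.mounting.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "AxisMap":
        vals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, rest = line.partition(":")
                vals[key.strip()] = np.array([int(t) for t in rest.split()], dtype=float).reshape(3, 3)
        return cls(mag_to_accel=vals.get("mag_to_accel", np.eye(3)), mounting=vals.get("mounting", np.eye(3)))


def apply_axis_map(table: SensorTable, axis_map: AxisMap, suffix: str = "_al") -> SensorTable:
    """Append axis-aligned accelerometer and magnetometer channels.

    Applying a map and then its inverse restores the original channels.
    """
    cols: dict[str, np.ndarray] = {}
    acc_names = table.schema.triad("accel")
    acc = table.triad("accel") @ axis_map.accel_matrix.T
    for i, n in enumerate(acc_names):
        cols[f"{n}{suffix}"] = acc[:, i]
    mag_names = table.schema.triad("mag")
    mag = table.triad("mag") @ axis_map.mag_matrix.T
    for i, n in enumerate(mag_names):
        cols[f"{n}{suffix}"] = mag[:, i]
    return table.with_columns(cols)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edges use the truncated window; NaNs are
    skipped within each window (and yield NaN only if the window is empty)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of samples")
    x = np.asarray(x, dtype=float)
    if window > x.shape[0]:
        raise ValueError(f"window ({window}) exceeds series length ({x.shape[0]})")
    df = pd.DataFrame(x)
    out = df.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out if x.ndim > 1 else out[:, 0]


def static_acceleration(accel: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Split raw acceleration into (static, dynamic) parts.

    ``static`` is the per-axis centred running mean over ``window`` samples
    (odd, >= 1); ``dynamic = raw - static`` exactly, so the two parts always
    recompose to the raw signal.
    """
    raw = np.asarray(accel, dtype=float)
    static = moving_average(raw, window)
    return static, raw - static


def pitch_roll(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and roll (degrees) from static acceleration vectors.

    ``pitch = atan2(-sx, hypot(sy, sz))``, ``roll = atan2(sy, sz)``.
    Zero-norm static vectors yield null angles.  At gimbal lock
    (|pitch| -> 90, vanishing ``hypot(sy, sz)``) roll is set to 0 by
    convention.
    """
    s = np.asarray(static, dtype=float)
    sx, sy, sz = s[..., 0], s[..., 1], s[..., 2]
    norm = np.sqrt(sx * sx + sy * sy + sz * sz)
    horiz = np.hypot(sy, sz)
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(-sx, horiz))
        roll = np.degrees(np.arctan2(sy, sz))
    roll = np.where(horiz <= _HORIZONTAL_EPS * np.where(norm > 0, norm, 1.0), 0.0, roll)
    bad = ~(norm > 0)
    pitch = np.where(bad, np.nan, pitch)
    roll = np.where(bad, np.nan, roll)
    return pitch, roll


def tilt_compensate(mag: np.ndarray, pitch_deg: np.ndarray, roll_deg: np.ndarray) -> np.ndarray:
    """Rotate magnetometer vectors level with the earth's surface.

    De-rotates by roll about x, then by pitch about y — the inverse of the
    attitude that carried gravity into the body frame — so the output x-y
    plane is horizontal.  Null attitude yields null output.
    """
    m = np.asarray(mag, dtype=float)
    phi = np.radians(np.asarray(roll_deg, dtype=float))
    theta = np.radians(np.asarray(pitch_deg, dtype=float))
    cphi, sphi = np.cos(phi), np.sin(phi)
    cth, sth = np.cos(theta), np.sin(theta)
    mx, my, mz = m[..., 0], m[..., 1], m[..., 2]
    # un-roll about x
    my1 = cphi * my - sphi * mz
    mz1 = sphi * my + cphi * mz
    # un-pitch about y
    lx = cth * mx + sth * mz1
    ly = my1
    lz = -sth * mx + cth * mz1
    return np.stack([lx, ly, lz], axis=-1)


def heading(level_mag: np.ndarray, declination_deg: float = 0.0) -> np.ndarray:
    """Compass heading (degrees, [0, 360)) from tilt-compensated magnetometer.

    ``H = atan2(m_y, -m_x)`` (the four-quadrant resolution of the ratio
    ``m_y / -m_x``), mapped to [0, 360); the declination is then added modulo
    360 to obtain a geographic heading.  Heading is null where the horizontal
    field component vanishes (undefined) or inputs are null.
    """
    if abs(declination_deg) > 180:
        raise ValueError("|declination| must be <= 180 degrees")
    m = np.asarray(level_mag, dtype=float)
    mx, my = m[..., 0], m[..., 1]
    total = np.linalg.norm(m, axis=-1)
    with np.errstate(invalid="ignore"):
        H = np.degrees(np.arctan2(my, -mx))
    H = np.mod(H + declination_deg, 360.0)
    horiz = np.hypot(mx, my)
    undefined = horiz <= _HORIZONTAL_EPS * np.where(total > 0, total, 1.0)
    H = np.where(undefined, np.nan, H)
    return H
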