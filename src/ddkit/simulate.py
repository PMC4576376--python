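"""Ground-truthed synthetic deployments for every stage of the tool chain.

The generator emulates a multi-sensor tag on a moving animal: a truth track
(headings, speeds, start position) is integrated on the spherical earth; the
tri-axial accelerometer reads rotated gravity plus a locomotion ("gait")
component plus noise; the tri-axial magnetometer reads the rotated earth
field pushed through a known soft-iron distortion and hard-iron offset (the
inverse of the calibration the pipeline must recover); positional fixes are
the truth positions at a fixed interval, optionally perturbed; behaviour
motifs are planted into a chosen channel at known positions.  Every
generating parameter is retained in the returned truth bundle so tests can
assert recovery, and the same seed always reproduces identical output.

Two deliberate constructions make the truth quantities exactly recoverable:

* the gait component is a quadrature pair ``A (cos wt, sin wt)`` on the x/y
  axes with the gait period dividing the smoothing window, so the windowed
  running mean of the gait is exactly zero away from the record edges and
  the per-sample VeDBA equals ``A`` — making the VeDBA-speed proxy exactly
  true by construction (``A = (speed - c) / m``);
* heading bias and speed scale errors are injected physically (a yaw
  mounting misalignment and a mis-scaled gait amplitude), so the derived
  channels carry exactly the systematic errors the fix correction must
  estimate.

The truth track integrator advances positions by rotating the position
vector in 3-D (``p' = p cos q + (n cos H + e sin H) sin q``), an
independent formulation of the spherical destination point against which
the dead-reckoning update can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChannelSchema, FixSet, SensorTable

__all__ = [
    "SimScenario",
    "simulate_deployment",
    "default_distortion",
    "motif_waveform",
    "planted_motif_series",
    "truth_destination_step",
]


def default_distortion() -> np.ndarray:
    """Default soft-iron distortion: SPD with axis gains 1.15/1.25/1.4.

    Magnetometer per-axis gain errors above unity are the common
    instrumental case; the matrix is rotated so the principal axes do not
    align with the sensor axes.
    """
    a = math.radians(30.0)
    Rz = np.array([[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]])
    return Rz @ np.diag([1.15, 1.25, 1.4]) @ Rz.T


@dataclass
class SimScenario:
    """Parameters of one synthetic deployment (defaults: noise-free, 10 min
    at 40 Hz, coastal-UK field geometry, constant modest attitude)."""

    seed: int = 0
    duration_s: float = 600.0
    rate_hz: float = 40.0
    start_lat: float = 51.6
    start_lon: float = -4.0
    # truth motion
    mean_speed_ms: float = 1.2
    speed_mode: str = "constant"  # "constant" or "gait"
    turn_rate_deg_s: float = 4.0  # RMS heading drift rate
    heading0_deg: float = 30.0
    pitch_deg: float = 4.0
    roll_deg: float = -3.0
    # geomagnetic field (unit magnitude; heading is scale-invariant)
    field_magnitude: float = 1.0
    inclination_deg: float = 66.0
    declination_deg: float = -2.0
    # magnetometer error model (raw = D @ field + b + noise)
    distortion: np.ndarray = field(default_factory=default_distortion)
    hard_iron: np.ndarray = field(default_factory=lambda: np.array([0.2, -0.1, 0.3]))
    accel_noise_g: float = 0.0
    mag_noise: float = 0.0
    # gait / speed model (VeDBA proxy is exact by construction)
    gait_period_samples: int = 5
    window_samples: int = 5
    speed_m: float = 3.0
    speed_c: float = 0.1
    speed_t: float = 0.05
    # injected systematic errors the fix correction must recover
    heading_bias_deg: float = 0.0
    speed_scale: float = 1.0
    # fixes
    fix_interval_s: float = 60.0
    fix_noise_m: float = 0.0
    # behaviour motifs (planted into `motif_channel`)
    n_motifs: int = 12
    motif_length: int = 61
    motif_channel: str = "pressure"
    motif_amplitude: float = 1.0
    # pre-deployment calibration cloud
    n_calibration: int = 500
    calibration_noise: float = 0.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    @property
    def dt_s(self) -> float:
        return 1.0 / self.rate_hz


def truth_destination_step(lat_deg: float, lon_deg: float, bearing_deg: float, q: float) -> tuple[float, float]:
    """Great-circle destination by 3-D rotation of the position vector."""
    la, lo, H = map(math.radians, (lat_deg, lon_deg, bearing_deg))
    p = np.array([math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)])
    north = np.array([-math.sin(la) * math.cos(lo), -math.sin(la) * math.sin(lo), math.cos(la)])
    east = np.array([-math.sin(lo), math.cos(lo), 0.0])
    p2 = p * math.cos(q) + (north * math.cos(H) + east * math.sin(H)) * math.sin(q)
    return math.degrees(math.asin(min(max(p2[2], -1.0), 1.0))), math.degrees(math.atan2(p2[1], p2[0]))


def _integrate_truth(scn: SimScenario, heading_deg: np.ndarray, speed_ms: np.ndarray, radius_m: float) -> tuple[np.ndarray, np.ndarray]:
    n = len(heading_deg)
    lat = np.empty(n)
    lon = np.empty(n)
    lat[0], lon[0] = scn.start_lat, scn.start_lon
    for i in range(1, n):
        q = speed_ms[i] * scn.dt_s / radius_m
        if q > 0:
            lat[i], lon[i] = truth_destination_step(lat[i - 1], lon[i - 1], heading_deg[i], q)
        else:
            lat[i], lon[i] = lat[i - 1], lon[i - 1]
    return lat, lon


def _rot_body(pitch_deg: float, roll_deg: float, yaw_deg: np.ndarray) -> np.ndarray:
    """(N, 3, 3) earth-to-body rotation R_x(roll) R_y(pitch) R_z(yaw)."""
    th = math.radians(pitch_deg)
    ph = math.radians(roll_deg)
    ps = np.radians(yaw_deg)
    Ry = np.array([[math.cos(th), 0, -math.sin(th)], [0, 1, 0], [math.sin(th), 0, math.cos(th)]])
    Rx = np.array([[1, 0, 0], [0, math.cos(ph), math.sin(ph)], [0, -math.sin(ph), math.cos(ph)]])
    c, s = np.cos(ps), np.sin(ps)
    Rz = np.zeros((len(ps), 3, 3))
    Rz[:, 0, 0] = c
    Rz[:, 0, 1] = s
    Rz[:, 1, 0] = -s
    Rz[:, 1, 1] = c
    Rz[:, 2, 2] = 1.0
    return np.einsum("ij,jk,nkl->nil", Rx, Ry, Rz)


def motif_waveform(length: int = 61, kind: str = "dive") -> np.ndarray:
    """A smooth, asymmetric motif (windowed multi-tone pulse)."""
    u = np.linspace(0.0, 1.0, length)
    env = np.sin(np.pi * u) ** 2
    if kind == "dive":
        return env * (np.sin(2 * np.pi * 3 * u) + 0.5 * np.sin(2 * np.pi * 7 * u + 0.7))
    if kind == "shake":
        return env * np.sin(2 * np.pi * 9 * u) * (1.0 - 0.6 * u)
    raise ValueError(f"unknown motif kind {kind!r}")


def _plant_positions(rng: np.random.Generator, n_samples: int, n_motifs: int, length: int) -> np.ndarray:
    """Non-overlapping random plant positions away from the record edges:
    one per equal-width bin of the usable span, jittered within its bin."""
    margin = 2 * length
    span = n_samples - 2 * margin - length
    bin_width = span // n_motifs if n_motifs else 0
    if n_motifs and bin_width < length + 11:
        raise ValueError("motifs too long for the series: cannot place them all")
    starts = [
        margin + k * bin_width + int(rng.integers(0, bin_width - length - 10))
        for k in range(n_motifs)
    ]
    return np.array(starts)


def planted_motif_series(
    seed: int,
    n_samples: int = 8000,
    motif: np.ndarray | None = None,
    n_instances: int = 20,
    snr_db: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A single-channel benchmark series: white noise with noisy motif copies.

    The noise level is set from the motif's mean square power so the planted
    copies sit at the requested signal-to-noise ratio.  Returns the series
    and the planted start indices.
    """
    rng = np.random.default_rng(seed)
    m = motif_waveform() if motif is None else np.asarray(motif, dtype=float)
    p_sig = float(np.mean(m * m))
    sigma = math.sqrt(p_sig / 10 ** (snr_db / 10.0))
    x = rng.normal(0.0, sigma, n_samples)
    starts = _plant_positions(rng, n_samples, n_instances, len(m))
    for s in starts:
        x[s : s + len(m)] += m
    return x, starts


def _time_fields(n: int, rate_hz: float) -> dict[str, np.ndarray]:
    dt_ms = 1000.0 / rate_hz
    t = np.round(np.arange(n) * dt_ms).astype(np.int64)
    return {
        "day": t // 86_400_000,
        "h": (t // 3_600_000) % 24,
        "min": (t // 60_000) % 60,
        "s": (t // 1_000) % 60,
        "ms": t % 1_000,
    }


def _calibration_cloud(scn: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Raw magnetometer readings from the pre-deployment rotation ritual:
    the device is swept through diverse orientations, so the true field
    vector samples the whole sphere before distortion."""
    u = rng.normal(size=(scn.n_calibration, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    raw = (scn.distortion @ (scn.field_magnitude * u).T).T + scn.hard_iron
    if scn.calibration_noise > 0:
        raw = raw + rng.normal(0.0, scn.calibration_noise, raw.shape)
    return raw


def simulate_deployment(scenario: SimScenario) -> tuple[SensorTable, FixSet, dict]:
    """Generate one deployment: sensor table, fix set and truth bundle.

    The truth bundle carries every generating quantity: truth headings,
    speeds, positions, attitude, the magnetometer error model, the
    calibration cloud, fix indices, planted motif positions and the motif
    waveform, plus the scenario itself.
    """
    scn = scenario
    if scn.speed_mode not in ("constant", "gait"):
        raise ValueError("speed_mode must be 'constant' or 'gait'")
    if scn.window_samples % scn.gait_period_samples != 0:
        raise ValueError("window must be a whole number of gait periods")
    n = scn.n_samples
    if scn.motif_length >= n:
        raise ValueError("motif longer than the series")
    rng = np.random.default_rng(scn.seed)

    # truth motion: smooth random-walk heading, constant speed
    dH = rng.normal(0.0, scn.turn_rate_deg_s * scn.dt_s, n)
    heading = np.mod(scn.heading0_deg + np.cumsum(dH), 360.0)
    speed = np.full(n, scn.mean_speed_ms)
    from .deadreckon import EARTH_RADIUS_M  # local import to avoid cycles

    lat, lon = _integrate_truth(scn, heading, speed, EARTH_RADIUS_M)

    # device yaw is magnetic (truth headings are geographic) and carries the
    # mounting misalignment (heading bias)
    yaw_dev = heading + scn.heading_bias_deg - scn.declination_deg
    R = _rot_body(scn.pitch_deg, scn.roll_deg, yaw_dev)

    # accelerometer: rotated gravity + quadrature gait + noise
    grav = R @ np.array([0.0, 0.0, 1.0])
    accel = grav.copy()
    if scn.speed_mode == "gait":
        A = (scn.speed_scale * speed - scn.speed_c) / scn.speed_m
        if np.any(A <= scn.speed_t):
            raise ValueError("gait amplitude would fall below the speed threshold")
        phase = 2 * np.pi * np.arange(n) / scn.gait_period_samples
        accel[:, 0] += A * np.cos(phase)
        accel[:, 1] += A * np.sin(phase)
    if scn.accel_noise_g > 0:
        accel = accel + rng.normal(0.0, scn.accel_noise_g, accel.shape)

    # magnetometer: rotated field through the error model
    inc = math.radians(scn.inclination_deg)
    f_e = scn.field_magnitude * np.array([-math.cos(inc), 0.0, math.sin(inc)])
    mag_true = R @ f_e
    mag = (scn.distortion @ mag_true.T).T + scn.hard_iron
    if scn.mag_noise > 0:
        mag = mag + rng.normal(0.0, scn.mag_noise, mag.shape)

    # environment channels; motifs planted into one of them
    pressure = np.zeros(n)
    temperature = np.full(n, 12.0)
    motif = motif_waveform(scn.motif_length)
    if scn.n_motifs > 0:
        starts = _plant_positions(rng, n, scn.n_motifs, scn.motif_length)
    else:
        starts = np.array([], dtype=int)
    channels = {"pressure": pressure, "temperature": temperature}
    target = channels[scn.motif_channel]
    for s0 in starts:
        target[s0 : s0 + scn.motif_length] += scn.motif_amplitude * motif

    df = pd.DataFrame(
        {
            **_time_fields(n, scn.rate_hz),
            "ax": accel[:, 0],
            "ay": accel[:, 1],
            "az": accel[:, 2],
            "mx": mag[:, 0],
            "my": mag[:, 1],
            "mz": mag[:, 2],
            "pressure": pressure,
            "temperature": temperature,
        }
    )
    table = SensorTable(df, ChannelSchema.infer(df.columns), rate_hz=scn.rate_hz, source=f"sim(seed={scn.seed})")

    # fixes: truth positions at the fix interval (+ optional noise in metres)
    step = int(round(scn.fix_interval_s * scn.rate_hz))
    fix_idx = np.arange(0, n, step)
    flat = lat[fix_idx].copy()
    flon = lon[fix_idx].copy()
    if scn.fix_noise_m > 0:
        dy = rng.normal(0.0, scn.fix_noise_m, len(fix_idx))
        dx = rng.normal(0.0, scn.fix_noise_m, len(fix_idx))
        flat = flat + np.degrees(dy / EARTH_RADIUS_M)
        flon = flon + np.degrees(dx / (EARTH_RADIUS_M * np.cos(np.radians(flat))))
    fixes = FixSet(t_ms=np.round(fix_idx * 1000.0 / scn.rate_hz), lat_deg=flat, lon_deg=flon)

    truth = {
        "scenario": scn,
        "heading_deg": heading,
        "speed_ms": speed,
        "pitch_deg": scn.pitch_deg,
        "roll_deg": scn.roll_deg,
        "lat_deg": lat,
        "lon_deg": lon,
        "fix_indices": fix_idx,
        "distortion": scn.distortion,
        "hard_iron": scn.hard_iron,
        "field_earth": f_e,
        "calibration_raw": _calibration_cloud(scn, rng),
        "motif": motif,
        "motif_starts": starts,
        "motif_channel": scn.motif_channel,
    }
    return table, fixes, truth
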