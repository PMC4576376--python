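"""Dead-reckoning on the spherical earth, with iterative ground-truth fix
correction.

Dead-reckoning integrates per-sample heading ``H`` and speed ``s`` from a
known start into a latitude/longitude track.  Each speed sample is converted
to an angular step ``q = s * dt / R`` with ``R = 6.371e6 m`` and the
position advanced with the spherical destination-point update

    lat_i = asin( sin lat_{i-1} cos q + cos lat_{i-1} sin q cos H )
    lon_i = lon_{i-1} + atan2( sin H sin q cos lat_{i-1},
                               cos q - sin lat_{i-1} sin lat_i )

Heading and speed are estimates, so systematic biases accumulate without
bound.  Where ground-truth fixes (e.g. GPS) are available, each inter-fix
segment is corrected by a constant heading coefficient ``hC`` added to every
sample heading and a speed coefficient ``sC`` multiplying every sample speed:

    hC = gpsHeading - drHeading        (bearing between segment endpoints)
    sC = gpsDistance / drDistance      (great-circle distance between them)

re-integrating from the segment's starting fix and iterating until the
adjustments fall below tolerance or an iteration cap is reached.  Each
accepted iteration tightens the path onto the fixes; the residual distance
at the closing fix is non-increasing by construction (a worsening candidate
step is rejected and iteration stops).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import FixSet

__all__ = [
    "EARTH_RADIUS_M",
    "GeoTrack",
    "SegmentCorrection",
    "dead_reckon",
    "fix_heading",
    "fix_distance",
    "correct_track",
]

#: spherical earth radius (m)
EARTH_RADIUS_M = 6.371e6


@dataclass
class GeoTrack:
    """Ordered latitude/longitude positions over time (degrees, ms)."""

    t_ms: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.lat_deg = np.asarray(self.lat_deg, dtype=float)
        self.lon_deg = np.asarray(self.lon_deg, dtype=float)
        if not (len(self.t_ms) == len(self.lat_deg) == len(self.lon_deg)):
            raise ValueError("track arrays must have equal length")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.lat_deg), initial=0.0) > 90.0 + 1e-12:
                raise ValueError("latitudes must lie in [-90, 90]")
        # wrap longitudes to (-180, 180]
        self.lon_deg = -np.mod(-self.lon_deg + 180.0, 360.0) + 180.0

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class SegmentCorrection:
    """Correction state for one inter-fix segment."""

    start_index: int
    end_index: int
    heading_coeff_deg: float
    speed_coeff: float
    iterations: int
    residual_m: float
    residual_log_m: list[float] = field(default_factory=list)
    fallback_constant_speed: bool = False


def _wrap180(angle_deg: float) -> float:
    """Wrap an angle to (-180, 180]."""
    return -((-angle_deg + 180.0) % 360.0) + 180.0


def _dr_steps(
    lat0: float,
    lon0: float,
    heading_deg: np.ndarray,
    q: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the printed destination update once per sample (radians in/out
    handled internally; inputs in degrees/radians as named).

    Null heading or step carries the position forward unchanged.
    """
    n = len(q)
    lat = np.empty(n)
    lon = np.empty(n)
    la = math.radians(lat0)
    lo = math.radians(lon0)
    H = np.radians(heading_deg)
    for i in range(n):
        qi = q[i]
        Hi = H[i]
        if qi > 0 and not (math.isnan(qi) or math.isnan(Hi)):
            sin_la = math.sin(la)
            cos_la = math.cos(la)
            cos_q = math.cos(qi)
            sin_q = math.sin(qi)
            la2 = math.asin(sin_la * cos_q + cos_la * sin_q * math.cos(Hi))
            lo = lo + math.atan2(math.sin(Hi) * sin_q * cos_la, cos_q - sin_la * math.sin(la2))
            la = la2
        lat[i] = la
        lon[i] = lo
    return np.degrees(lat), np.degrees(lon)


def dead_reckon(
    heading_deg: np.ndarray,
    speed_ms: np.ndarray,
    dt_s: float | np.ndarray,
    start: tuple[float, float],
    t_ms: np.ndarray | None = None,
    radius_m: float = EARTH_RADIUS_M,
) -> GeoTrack:
    """Integrate heading and speed into a :class:`GeoTrack`.

    The track has the same length as the input series; the first point is
    the start position and sample ``i`` (i >= 1) advances from sample
    ``i-1`` by the angular distance ``q_i = speed_i * dt_i / R`` along
    heading ``H_i``.  Zero-distance steps and null heading/speed samples
    leave the position unchanged.

    Raises if the start lies at a pole while any step has nonzero distance
    (longitude undefined there).
    """
    H = np.asarray(heading_deg, dtype=float)
    s = np.asarray(speed_ms, dtype=float)
    if H.shape != s.shape:
        raise ValueError("heading and speed series must be aligned")
    dt = np.broadcast_to(np.asarray(dt_s, dtype=float), s.shape)
    lat0, lon0 = float(start[0]), float(start[1])
    if not (math.isfinite(lat0) and math.isfinite(lon0)):
        raise ValueError("start position must be finite")
    q = s * dt / radius_m
    if abs(lat0) >= 90.0 and np.nansum(q[1:]) > 0:
        raise ValueError("start position at a pole: longitude undefined")
    lat, lon = _dr_steps(lat0, lon0, H[1:], q[1:])
    lat = np.concatenate([[lat0], lat])
    lon = np.concatenate([[lon0], lon])
    if t_ms is None:
        t_ms = np.concatenate([[0.0], np.cumsum(dt[1:])]) * 1000.0
    return GeoTrack(t_ms=np.asarray(t_ms, dtype=float), lat_deg=lat, lon_deg=lon, start=(lat0, lon0))


def fix_heading(p0: tuple[float, float], p1: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``p0`` to ``p1``, degrees in [0, 360).

    Computed with the two-argument arctangent
    ``atan2(sin dlon * cos lat1, cos lat0 sin lat1 - sin lat0 cos lat1 cos dlon)``
    and consistent with :func:`dead_reckon` in the round-trip sense: one
    dead-reckoned step of length ``fix_distance(p0, p1)`` along this bearing
    lands on ``p1``.
    """
    if tuple(p0) == tuple(p1):
        raise ValueError("bearing undefined for identical points")
    la0, lo0 = math.radians(p0[0]), math.radians(p0[1])
    la1, lo1 = math.radians(p1[0]), math.radians(p1[1])
    dlon = lo1 - lo0
    y = math.sin(dlon) * math.cos(la1)
    x = math.cos(la0) * math.sin(la1) - math.sin(la0) * math.cos(la1) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def fix_distance(p0: tuple[float, float], p1: tuple[float, float], radius_m: float = EARTH_RADIUS_M) -> float:
    """Great-circle (haversine) distance between two points, metres.

    ``arcDist = sin^2(latD/2) + sin^2(lonD/2) cos(lat0) cos(lat1)``;
    ``d = R * 2 * atan2(sqrt(arcDist), sqrt(1 - arcDist))``.  Symmetric and
    non-negative.
    """
    la0, lo0 = math.radians(p0[0]), math.radians(p0[1])
    la1, lo1 = math.radians(p1[0]), math.radians(p1[1])
    sd_lat = math.sin((la1 - la0) / 2.0)
    sd_lon = math.sin((lo1 - lo0) / 2.0)
    arc = sd_lat * sd_lat + sd_lon * sd_lon * math.cos(la0) * math.cos(la1)
    arc = min(max(arc, 0.0), 1.0)
    return radius_m * 2.0 * math.atan2(math.sqrt(arc), math.sqrt(1.0 - arc))


def _fix_indices(track_t_ms: np.ndarray, fixes: FixSet) -> np.ndarray:
    """Sample index of each fix (nearest sample; fixes must lie in the span)."""
    t = np.asarray(track_t_ms, dtype=float)
    if len(fixes) < 2:
        raise ValueError("at least two fixes are required for correction")
    if fixes.t_ms[0] < t[0] - 1e-9 or fixes.t_ms[-1] > t[-1] + 1e-9:
        raise ValueError("fix timestamps fall outside the track's time span")
    pos = np.searchsorted(t, fixes.t_ms)
    pos = np.clip(pos, 0, len(t) - 1)
    left = np.clip(pos - 1, 0, len(t) - 1)
    idx = np.where(np.abs(t[left] - fixes.t_ms) < np.abs(t[pos] - fixes.t_ms), left, pos)
    if np.any(np.diff(idx) < 1):
        raise ValueError("each inter-fix segment must contain at least one sample")
    return idx.astype(int)


def correct_track(
    track: GeoTrack,
    heading_deg: np.ndarray,
    speed_ms: np.ndarray,
    fixes: FixSet,
    dt_s: float | np.ndarray | None = None,
    max_iter: int = 10,
    tol_m: float = 1.0,
    heading_tol_deg: float = 0.1,
    speed_tol: float = 0.001,
    radius_m: float = EARTH_RADIUS_M,
) -> tuple[GeoTrack, list[SegmentCorrection]]:
    """Iteratively force a dead-reckoned track through ground-truth fixes.

    For every segment between consecutive fixes the per-sample headings are
    offset by a constant ``hC`` and the speeds scaled by ``sC`` so that the
    re-integrated segment (anchored at the opening fix, which resets the
    accumulated error) ends on the closing fix.  Iteration stops when the
    incremental adjustments drop below ``heading_tol_deg`` / ``speed_tol``,
    when the endpoint residual drops below ``tol_m`` metres, after
    ``max_iter`` accepted iterations, or when a candidate step would worsen
    the residual (rejected, keeping the log non-increasing).

    If a segment dead-reckons to zero length while the fixes are apart, the
    speed coefficient is undefined; the segment is flagged and a constant
    (uniform) speed profile covering the fix-to-fix distance is substituted.

    Returns the corrected track (first point forced to the first fix;
    samples after the last fix continue with the last segment's corrections)
    and the per-segment correction records.
    """
    H = np.asarray(heading_deg, dtype=float)
    s = np.asarray(speed_ms, dtype=float)
    if len(H) != len(track) or len(s) != len(track):
        raise ValueError("heading/speed series must align with the track")
    if dt_s is None:
        dt = np.concatenate([[0.0], np.diff(track.t_ms) / 1000.0])
    else:
        dt = np.broadcast_to(np.asarray(dt_s, dtype=float), s.shape)
    q_all = np.where(np.isnan(s), 0.0, s) * dt / radius_m
    H_all = H.copy()
    idx = _fix_indices(track.t_ms, fixes)

    lat_out = track.lat_deg.copy()
    lon_out = track.lon_deg.copy()
    # samples before the first fix are left as supplied; the corrected path
    # itself starts at the first fix
    lat_out[idx[0]] = fixes.lat_deg[0]
    lon_out[idx[0]] = fixes.lon_deg[0]

    segments: list[SegmentCorrection] = []
    for k in range(len(idx) - 1):
        i0, i1 = idx[k], idx[k + 1]
        p_start = (fixes.lat_deg[k], fixes.lon_deg[k])
        p_end = (fixes.lat_deg[k + 1], fixes.lon_deg[k + 1])
        Hseg = H_all[i0 + 1 : i1 + 1]
        qseg = q_all[i0 + 1 : i1 + 1].copy()
        gps_dist = fix_distance(p_start, p_end, radius_m)
        fallback = False
        if np.nansum(qseg) * radius_m <= 0.0 < gps_dist:
            # dead-reckoned segment has zero length: sC undefined; substitute
            # a uniform speed profile covering the fix-to-fix distance
            fallback = True
            qseg = np.full(len(qseg), gps_dist / radius_m / max(len(qseg), 1))
        hC, sC = 0.0, 1.0
        lat_seg, lon_seg = _dr_steps(p_start[0], p_start[1], Hseg + hC, qseg * sC)
        resid = fix_distance((lat_seg[-1], lon_seg[-1]), p_end, radius_m) if len(lat_seg) else 0.0
        residual_log = [resid]
        iterations = 0
        while iterations < max_iter and len(lat_seg):
            dr_endpoint = (lat_seg[-1], lon_seg[-1])
            dr_dist = fix_distance(p_start, dr_endpoint, radius_m)
            if gps_dist == 0.0:
                break
            if dr_dist == 0.0:
                # collapsed under iteration; bail out to the uniform profile
                fallback = True
                qseg = np.full(len(qseg), gps_dist / radius_m / max(len(qseg), 1))
                sC = 1.0
                lat_seg, lon_seg = _dr_steps(p_start[0], p_start[1], Hseg + hC, qseg * sC)
                resid = fix_distance((lat_seg[-1], lon_seg[-1]), p_end, radius_m)
                residual_log.append(resid)
                iterations += 1
                continue
            gps_heading = fix_heading(p_start, p_end)
            dr_heading = fix_heading(p_start, dr_endpoint)
            d_h = _wrap180(gps_heading - dr_heading)
            d_s = gps_dist / dr_dist
            if abs(d_h) < heading_tol_deg and abs(d_s - 1.0) < speed_tol:
                break
            cand_hC = _wrap180(hC + d_h)
            cand_sC = sC * d_s
            lat_c, lon_c = _dr_steps(p_start[0], p_start[1], Hseg + cand_hC, qseg * cand_sC)
            resid_c = fix_distance((lat_c[-1], lon_c[-1]), p_end, radius_m)
            if resid_c > resid:
                break  # reject worsening step; residual log stays monotone
            hC, sC = cand_hC, cand_sC
            lat_seg, lon_seg = lat_c, lon_c
            resid = resid_c
            residual_log.append(resid)
            iterations += 1
            if resid < tol_m:
                break
        lat_out[i0 + 1 : i1 + 1] = lat_seg
        lon_out[i0 + 1 : i1 + 1] = lon_seg
        # reset accumulated error: the closing fix anchors the next segment
        lat_out[i1] = fixes.lat_deg[k + 1]
        lon_out[i1] = fixes.lon_deg[k + 1]
        segments.append(
            SegmentCorrection(
                start_index=int(i0),
                end_index=int(i1),
                heading_coeff_deg=hC,
                speed_coeff=sC,
                iterations=iterations,
                residual_m=resid,
                residual_log_m=residual_log,
                fallback_constant_speed=fallback,
            )
        )

    # tail after the last fix: continue from the fix with the last segment's
    # correction applied (best local estimate of the systematic biases)
    i_last = idx[-1]
    if i_last < len(track) - 1:
        hC = segments[-1].heading_coeff_deg if segments else 0.0
        sC = segments[-1].speed_coeff if segments else 1.0
        lat_t, lon_t = _dr_steps(
            fixes.lat_deg[-1],
            fixes.lon_deg[-1],
            H_all[i_last + 1 :] + hC,
            q_all[i_last + 1 :] * sC,
        )
        lat_out[i_last + 1 :] = lat_t
        lon_out[i_last + 1 :] = lon_t

    corrected = GeoTrack(
        t_ms=track.t_ms.copy(),
        lat_deg=lat_out,
        lon_deg=lon_out,
        start=(float(fixes.lat_deg[0]), float(fixes.lon_deg[0])),
    )
    return corrected, segments
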