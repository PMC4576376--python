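"""Delimited sensor-log I/O, channel schemas, time indexing and fix merging.

Smart animal tags (tri-axial accelerometer + magnetometer plus environmental
sensors, sampled at infra-second rates) export their deployments as CSV or
tab-delimited tables, one row per sample, with the wall-clock split over
``day / hour / min / sec / ms`` columns.  Positional fixes (e.g. GPS) arrive
in a second file on the same clock.  This module loads both, maintains a
typed channel schema, merges fixes into the sample table by exact timestamp,
and exports the merged table (raw + derived channels + integer behaviour
codes) back to CSV such that a reload reproduces the numeric content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "TIME_ROLES",
    "Channel",
    "ChannelSchema",
    "SensorTable",
    "FixSet",
    "load_table",
    "load_fixes",
    "merge_fixes",
    "export_merged",
]

#: semantic roles a channel may take
ROLES = frozenset(
    {
        "time-day",
        "time-hour",
        "time-min",
        "time-sec",
        "time-ms",
        "accel-x",
        "accel-y",
        "accel-z",
        "mag-x",
        "mag-y",
        "mag-z",
        "pressure",
        "temperature",
        "latitude",
        "longitude",
        "derived",
        "other",
    }
)

TIME_ROLES = ("time-day", "time-hour", "time-min", "time-sec", "time-ms")

#: milliseconds contributed by one unit of each time-* field
_TIME_FACTORS_MS = {
    "time-day": 86_400_000,
    "time-hour": 3_600_000,
    "time-min": 60_000,
    "time-sec": 1_000,
    "time-ms": 1,
}

DTYPES = ("integer", "real", "text")

# column-name conventions used to auto-resolve roles on import
_NAME_TO_ROLE = {
    "day": "time-day",
    "d": "time-day",
    "h": "time-hour",
    "hour": "time-hour",
    "hours": "time-hour",
    "m": "time-min",
    "min": "time-min",
    "mins": "time-min",
    "s": "time-sec",
    "sec": "time-sec",
    "secs": "time-sec",
    "ms": "time-ms",
    "msec": "time-ms",
    "ax": "accel-x",
    "ay": "accel-y",
    "az": "accel-z",
    "acc_x": "accel-x",
    "acc_y": "accel-y",
    "acc_z": "accel-z",
    "mx": "mag-x",
    "my": "mag-y",
    "mz": "mag-z",
    "mag_x": "mag-x",
    "mag_y": "mag-y",
    "mag_z": "mag-z",
    "pressure": "pressure",
    "temp": "temperature",
    "temperature": "temperature",
    "lat": "latitude",
    "latitude": "latitude",
    "lon": "longitude",
    "long": "longitude",
    "longitude": "longitude",
}


@dataclass(frozen=True)
class Channel:
    """One column of a sensor log: its name, semantic role and value type."""

    name: str
    role: str = "other"
    dtype: str = "real"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown channel dtype {self.dtype!r}")


@dataclass(frozen=True)
class ChannelSchema:
    """Typed description of every channel in a :class:`SensorTable`.

    Invariants: channel names are unique, each ``time-*`` role appears at
    most once, and accelerometer/magnetometer roles are real-valued.
    """

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        for role in TIME_ROLES:
            if sum(c.role == role for c in self.channels) > 1:
                raise ValueError(f"at most one channel may have role {role!r}")
        for c in self.channels:
            if (c.role.startswith("accel-") or c.role.startswith("mag-")) and c.dtype != "real":
                raise ValueError(f"channel {c.name!r} with role {c.role!r} must be real-valued")

    @classmethod
    def from_channels(cls, channels: Iterable[Channel]) -> "ChannelSchema":
        return cls(tuple(channels))

    @classmethod
    def infer(cls, names: Sequence[str]) -> "ChannelSchema":
        """Guess roles from conventional column names; unknown names get 'other'."""
        chans = []
        for n in names:
            role = _NAME_TO_ROLE.get(n.strip().lower(), "other")
            dtype = "integer" if role.startswith("time-") else "real"
            chans.append(Channel(n, role, dtype))
        return cls(tuple(chans))

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    def by_role(self, role: str) -> list[Channel]:
        return [c for c in self.channels if c.role == role]

    def name_of(self, role: str) -> str:
        hits = self.by_role(role)
        if not hits:
            raise KeyError(f"no channel with role {role!r}")
        return hits[0].name

    def triad(self, prefix: str) -> list[str]:
        """Channel names for a tri-axial sensor, e.g. ``triad('accel')``."""
        return [self.name_of(f"{prefix}-{ax}") for ax in "xyz"]

    def has_role(self, role: str) -> bool:
        return any(c.role == role for c in self.channels)

    def with_channel(self, channel: Channel) -> "ChannelSchema":
        return ChannelSchema(self.channels + (channel,))


@dataclass
class SensorTable:
    """A time-indexed multichannel sensor log (raw plus derived columns).

    ``t_ms`` is milliseconds since the first sample, combined from the five
    time-* fields as ``day*86400000 + h*3600000 + min*60000 + s*1000 + ms``;
    ``t0_ms`` retains the absolute value of the first sample so that tables
    and fix sets sharing a clock can be aligned.  Appending a derived column
    never changes existing values or the row count.
    """

    data: pd.DataFrame
    schema: ChannelSchema
    rate_hz: float | None = None
    n_malformed: int = 0
    source: str = ""
    _t_ms: np.ndarray | None = field(default=None, repr=False, compare=False)
    _t0_ms: float = field(default=0.0, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("sensor table must contain at least one row")
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise ValueError(f"schema channels absent from data: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_time_index(self) -> bool:
        return any(self.schema.has_role(r) for r in TIME_ROLES) or self.rate_hz is not None

    def _compute_time(self) -> None:
        time_chans = [(c, _TIME_FACTORS_MS[c.role]) for c in self.schema.channels if c.role in _TIME_FACTORS_MS]
        if time_chans:
            total = np.zeros(len(self.data))
            for c, factor in time_chans:
                total = total + self.data[c.name].to_numpy(dtype=float) * factor
            self._t0_ms = float(total[0])
            t = total - self._t0_ms
        elif self.rate_hz is not None:
            self._t0_ms = 0.0
            t = np.arange(len(self.data)) * (1000.0 / self.rate_hz)
        else:
            raise ValueError("no time-* channels and no nominal rate: a time index is required")
        if np.any(np.diff(t) < 0):
            raise ValueError("sample timestamps must be non-decreasing")
        self._t_ms = t

    @property
    def t_ms(self) -> np.ndarray:
        """Per-sample timestamp in milliseconds since the first sample."""
        if self._t_ms is None:
            self._compute_time()
        return self._t_ms

    @property
    def t0_ms(self) -> float:
        if self._t_ms is None:
            self._compute_time()
        return self._t0_ms

    @property
    def abs_t_ms(self) -> np.ndarray:
        """Timestamps on the absolute (file) clock, for fix alignment."""
        return self.t0_ms + self.t_ms

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def triad(self, prefix: str) -> np.ndarray:
        """(N, 3) array of a tri-axial sensor's channels (``accel`` or ``mag``)."""
        return self.data[self.schema.triad(prefix)].to_numpy(dtype=float)

    def with_column(
        self, name: str, values, role: str = "derived", dtype: str = "real", overwrite: bool = False
    ) -> "SensorTable":
        """Return a new table with one derived column appended.

        An existing column of the same name is an error unless
        ``overwrite=True`` (used when re-running a stage on its own output).
        """
        values = np.asarray(values)
        if len(values) != len(self.data):
            raise ValueError(f"column {name!r} has {len(values)} values for {len(self.data)} rows")
        exists = name in self.data.columns
        if exists and not overwrite:
            raise ValueError(f"column {name!r} already exists")
        df = self.data.copy()
        df[name] = values
        schema = self.schema if exists else self.schema.with_channel(Channel(name, role, dtype))
        return replace(
            self,
            data=df,
            schema=schema,
            _t_ms=self._t_ms,
            _t0_ms=self._t0_ms,
        )

    def with_columns(self, cols: dict[str, np.ndarray], role: str = "derived", overwrite: bool = False) -> "SensorTable":
        out = self
        for name, values in cols.items():
            out = out.with_column(name, values, role=role, overwrite=overwrite)
        return out


@dataclass(frozen=True)
class FixSet:
    """Time-stamped positional fixes (e.g. GPS) on the sample table's clock."""

    t_ms: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray
    source: str = "gps"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        lat = np.asarray(self.lat_deg, dtype=float)
        lon = np.asarray(self.lon_deg, dtype=float)
        if not (len(t) == len(lat) == len(lon)):
            raise ValueError("fix arrays must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("fix timestamps must be strictly increasing")
        if len(lat) and (np.nanmax(np.abs(lat)) > 90 or np.nanmax(np.abs(lon)) > 180):
            raise ValueError("fix coordinates out of range (|lat|<=90, |lon|<=180)")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "lat_deg", lat)
        object.__setattr__(self, "lon_deg", lon)

    def __len__(self) -> int:
        return len(self.t_ms)


def _coerce_numeric(df: pd.DataFrame, schema: ChannelSchema) -> tuple[pd.DataFrame, int]:
    """Convert numeric channels in-place; malformed cells become NaN and are counted."""
    n_malformed = 0
    for c in schema.channels:
        if c.dtype == "text" or c.name not in df.columns:
            continue
        col = df[c.name]
        if col.dtype == object:
            conv = pd.to_numeric(col, errors="coerce")
            bad = conv.isna() & col.notna() & (col.astype(str).str.strip() != "")
            n_malformed += int(bad.sum())
            df[c.name] = conv
        elif not pd.api.types.is_numeric_dtype(col):
            df[c.name] = pd.to_numeric(col, errors="coerce")
    return df, n_malformed


def load_table(
    path,
    delimiter: str = ",",
    schema: ChannelSchema | None = None,
    rate_hz: float | None = None,
) -> SensorTable:
    """Load a delimited sensor log into a typed :class:`SensorTable`.

    Parameters
    ----------
    path : str or file-like
        CSV or tab-delimited text with a header row.
    delimiter : str
        ``","`` or ``"\\t"``.
    schema : ChannelSchema, optional
        Channel typing; when omitted, roles are inferred from column names.
    rate_hz : float, optional
        Nominal sampling rate; required for a time index only when the file
        carries no time-* channels.

    Malformed numeric cells become missing values; their count is reported on
    ``SensorTable.n_malformed``.  Rows with the wrong column count raise a
    ``ValueError`` naming the offending row.
    """
    if delimiter not in (",", "\t"):
        raise ValueError("delimiter must be a comma or a tab")
    try:
        # round_trip float parsing: an export -> import cycle must preserve
        # every numeric value bit-for-bit
        df = pd.read_csv(path, sep=delimiter, header=0, skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # C parser reports the 1-based line
        raise ValueError(f"malformed row: {exc}") from exc
    except OSError as exc:
        raise ValueError(f"cannot read {path!r}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if schema is None:
        schema = ChannelSchema.infer(df.columns)
    else:
        extra = [c for c in df.columns if c not in schema.names]
        if extra:
            # auto-name: unschema'd columns are carried as untyped extras
            schema = ChannelSchema(schema.channels + tuple(Channel(n, "other", "real") for n in extra))
    df, n_malformed = _coerce_numeric(df, schema)
    return SensorTable(df, schema, rate_hz=rate_hz, n_malformed=n_malformed, source=str(path))


def load_fixes(path, delimiter: str = ",", source: str = "gps") -> FixSet:
    """Load positional fixes from CSV: either split time fields plus lat/lon,
    or ``t_ms,lat,lon`` columns."""
    df = pd.read_csv(path, sep=delimiter, header=0, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    lat_col = next((c for c in df.columns if c in ("lat", "latitude")), None)
    lon_col = next((c for c in df.columns if c in ("lon", "long", "longitude")), None)
    if lat_col is None or lon_col is None:
        raise ValueError("fix file must contain latitude and longitude columns")
    if "t_ms" in df.columns:
        t = df["t_ms"].to_numpy(dtype=float)
    else:
        schema = ChannelSchema.infer(df.columns)
        t = np.zeros(len(df))
        found = False
        for c in schema.channels:
            if c.role in _TIME_FACTORS_MS:
                t = t + df[c.name].to_numpy(dtype=float) * _TIME_FACTORS_MS[c.role]
                found = True
        if not found:
            raise ValueError("fix file needs a t_ms column or time-* fields")
    return FixSet(t, df[lat_col].to_numpy(dtype=float), df[lon_col].to_numpy(dtype=float), source=source)


def save_fixes(fixes: FixSet, path) -> None:
    pd.DataFrame({"t_ms": fixes.t_ms, "lat": fixes.lat_deg, "lon": fixes.lon_deg}).to_csv(path, index=False)


def merge_fixes(
    table: SensorTable,
    fixes: FixSet,
    tolerance_ms: float = 0.0,
    lat_name: str = "fix_lat",
    lon_name: str = "fix_lon",
) -> SensorTable:
    """Append fix latitude/longitude columns to the table by timestamp match.

    Both inputs are assumed time-synchronised on the same clock.  A row gets
    fix values iff a fix shares its exact timestamp; every other row gets
    null.  No interpolation is performed at merge time.  ``tolerance_ms > 0``
    optionally enables nearest-sample matching within that tolerance
    (off by default).
    """
    t = table.abs_t_ms
    n = len(table)
    lat = np.full(n, np.nan)
    lon = np.full(n, np.nan)
    n_matched = 0
    for ft, flat, flon in zip(fixes.t_ms, fixes.lat_deg, fixes.lon_deg):
        lo = np.searchsorted(t, ft - tolerance_ms, side="left")
        hi = np.searchsorted(t, ft + tolerance_ms, side="right")
        if hi > lo:
            idx = lo + int(np.argmin(np.abs(t[lo:hi] - ft)))
            lat[idx] = flat
            lon[idx] = flon
            n_matched += 1
    if len(fixes) and n_matched == 0:
        warnings.warn(
            f"none of the {len(fixes)} fixes fall on the table's time stamps; "
            "merged position columns are all null",
            stacklevel=2,
        )
    out = table.with_column(lat_name, lat, role="latitude")
    out = out.with_column(lon_name, lon, role="longitude")
    return out


def export_merged(table: SensorTable, labels=None, path=None, behaviour_name: str = "behaviour") -> None:
    """Write the table (original + derived channels) plus one behaviour-code
    column to CSV.

    A row inside a labelled region carries that behaviour's integer code;
    unlabelled rows carry 0.  Overlapping labels of different classes are an
    error (raised by the label set); reloading the file reproduces the
    numeric content exactly (floats are written with round-trippable repr).
    """
    if path is None:
        raise ValueError("an output path is required")
    df = table.data.copy()
    if labels is not None:
        codes = labels.behaviour_codes(len(df))
    else:
        codes = np.zeros(len(df), dtype=np.int64)
    df[behaviour_name] = codes
    # %.17g round-trips IEEE doubles exactly, keeping re-export idempotent
    df.to_csv(path, index=False, float_format="%.17g")
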