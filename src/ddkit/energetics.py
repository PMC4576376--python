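"""Dynamic body acceleration (VeDBA / ODBA) and the VeDBA-to-speed model.

Dynamic body acceleration is the movement-induced residual of the raw
acceleration after the gravity-dominated running mean is removed.  Two
scalar summaries are in common use as proxies for metabolic rate (VO2):

* ``VeDBA = sqrt(DA_x^2 + DA_y^2 + DA_z^2)`` — the vectorial sum, and
* ``ODBA  = DA_x + DA_y + DA_z``            — the overall (L1) sum,

where ``DA_i = |raw_i - running_mean_i|`` per axis.  For any sample the norm
inequalities ``ODBA / sqrt(3) <= VeDBA <= ODBA`` hold.  VeDBA additionally
proxies speed during terrestrial locomotion; the speed model is the
thresholded linear rule

    s = VeDBA * m + c   if VeDBA > t,   else 0

with coefficient ``m`` (m/s per g), constant ``c`` (m/s) and threshold ``t``
(g).  For animals whose VeDBA does not track speed (e.g. volant species) a
constant-speed mode is provided instead; the resulting track is then
corrected against positional fixes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attitude import moving_average

__all__ = ["SpeedModel", "dynamic_acceleration", "speed_from_vedba"]


@dataclass(frozen=True)
class SpeedModel:
    """VeDBA-to-speed parameters, or a constant-speed setting.

    ``mode`` is ``"vedba"`` (thresholded linear rule) or ``"constant"``.
    """

    m: float = 1.0
    c: float = 0.0
    t: float = 0.0
    mode: str = "vedba"
    constant: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("vedba", "constant"):
            raise ValueError("mode must be 'vedba' or 'constant'")
        if self.m < 0 or self.c < 0 or self.t < 0 or self.constant < 0:
            raise ValueError("speed model parameters must be non-negative")


def dynamic_acceleration(accel: np.ndarray, window: int) -> pd.DataFrame:
    """Per-axis dynamic acceleration plus VeDBA and ODBA.

    Parameters
    ----------
    accel : (N, 3) array
        Raw tri-axial acceleration in g.
    window : int
        Odd window (samples) for the centred running mean; the same
        windowing as the static/dynamic split for attitude, though the two
        may be set independently.

    Returns a DataFrame with columns ``da_x, da_y, da_z, vedba, odba``.
    Nulls propagate.
    """
    raw = np.asarray(accel, dtype=float)
    da = np.abs(raw - moving_average(raw, window))
    vedba = np.sqrt(np.sum(da * da, axis=1))
    odba = np.sum(da, axis=1)
    return pd.DataFrame({"da_x": da[:, 0], "da_y": da[:, 1], "da_z": da[:, 2], "vedba": vedba, "odba": odba})


def speed_from_vedba(vedba: np.ndarray, model: SpeedModel) -> np.ndarray:
    """Speed (m/s) from VeDBA under the thresholded linear rule.

    ``s = VeDBA*m + c`` where ``VeDBA > t`` (strict), else 0; in constant
    mode every sample gets the constant.  Nulls propagate.
    """
    v = np.asarray(vedba, dtype=float)
    if model.mode == "constant":
        s = np.full(v.shape, model.constant)
    else:
        with np.errstate(invalid="ignore"):
            s = np.where(v > model.t, v * model.m + model.c, 0.0)
    return np.where(np.isnan(v), np.nan, s)
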