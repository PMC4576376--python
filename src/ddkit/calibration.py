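"""Magnetometer hard-iron / soft-iron calibration by ellipsoid fitting.

An error-free tri-axial magnetometer rotated through all orientations traces
a sphere centred on the origin.  Hard-iron effects (constant bias fields)
displace that sphere; soft-iron effects (ferrous material distorting the
ambient field) stretch it into an ellipsoid.  Calibration therefore amounts
to fitting an ellipsoid to a cloud of readings taken at diverse orientations
and deriving the affine map that restores the sphere:

    corrected(x) = W (x - b)

where ``b`` is the ellipsoid centre (hard-iron offset) and ``W`` the
symmetric positive-definite square root of the ellipsoid's shape matrix
(soft-iron correction).  The fit is the standard algebraic least-squares fit
of the general quadric ``x'Mx + 2g'x = 1`` followed by extraction of
``b = -M^{-1} g`` and ``W = sqrtm(M / (1 + g'M^{-1}g))``.  The global scale
of ``W`` is normalised so the mean corrected norm equals one; heading is
scale-invariant so this is purely cosmetic.  Fit quality is reported as the
coefficient of variation of the corrected vector norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import SensorTable

__all__ = [
    "CalibrationModel",
    "fit_ellipsoid",
    "apply_calibration",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Hard-iron offset ``b`` and soft-iron correction matrix ``W``.

    ``W`` is symmetric positive-definite; ``field_magnitude`` is the mean
    corrected norm of the fitting samples (unity by normalisation) and
    ``fit_cv`` the coefficient of variation of those norms.
    """

    offset: np.ndarray
    matrix: np.ndarray
    field_magnitude: float = 1.0
    fit_cv: float = 0.0

    def __post_init__(self) -> None:
        b = np.asarray(self.offset, dtype=float).reshape(3)
        W = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if not np.allclose(W, W.T, atol=1e-9 * max(1.0, float(np.abs(W).max()))):
            raise ValueError("correction matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(0.5 * (W + W.T)) <= 0):
            raise ValueError("correction matrix must be positive-definite")
        object.__setattr__(self, "offset", b)
        object.__setattr__(self, "matrix", 0.5 * (W + W.T))

    def apply(self, samples: np.ndarray) -> np.ndarray:
        """Map raw readings (N, 3) onto the calibrated sphere; NaN propagates."""
        x = np.asarray(samples, dtype=float)
        return (x - self.offset) @ self.matrix.T


def fit_ellipsoid(samples: np.ndarray) -> CalibrationModel:
    """Fit an ellipsoid to raw magnetometer readings and derive the correction.

    Parameters
    ----------
    samples : (N, 3) array
        Readings spanning diverse orientations, N >= 10.

    Raises
    ------
    ValueError
        If the cloud is degenerate (rank < 3 / points near a plane), the fit
        cannot constrain all three axes: "insufficient orientation coverage".
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.any(np.isnan(x), axis=1)]
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("samples must be an (N, 3) array")
    if len(x) < 10:
        raise ValueError("at least 10 samples are required to fit the ellipsoid")
    centred = x - x.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] == 0 or sv[2] / sv[0] < 1e-6:
        raise ValueError("insufficient orientation coverage: samples are rank-deficient (near a plane)")

    # algebraic quadric fit  x'Mx + 2g'x = 1
    X, Y, Z = x[:, 0], x[:, 1], x[:, 2]
    D = np.column_stack([X * X, Y * Y, Z * Z, 2 * X * Y, 2 * X * Z, 2 * Y * Z, 2 * X, 2 * Y, 2 * Z])
    p, *_ = np.linalg.lstsq(D, np.ones(len(x)), rcond=None)
    M = np.array(
        [
            [p[0], p[3], p[4]],
            [p[3], p[1], p[5]],
            [p[4], p[5], p[2]],
        ]
    )
    g = p[6:9]
    # the RHS=1 normalisation flips the sign of M when the origin lies
    # outside the ellipsoid; Q = M / (1 + g'M^-1 g) restores a positive
    # definite shape either way, so only a mixed-sign M is degenerate
    eig = np.linalg.eigvalsh(M)
    if np.any(eig == 0) or (np.any(eig < 0) and np.any(eig > 0)):
        raise ValueError("insufficient orientation coverage: fitted quadric is not an ellipsoid")
    b = -np.linalg.solve(M, g)
    k = 1.0 + g @ np.linalg.solve(M, g)
    Q = M / k  # (x-b)'Q(x-b) = 1 on the fitted surface
    if np.any(np.linalg.eigvalsh(Q) <= 0):
        raise ValueError("insufficient orientation coverage: degenerate ellipsoid scale")
    W = scipy.linalg.sqrtm(Q).real
    W = 0.5 * (W + W.T)

    norms = np.linalg.norm((x - b) @ W.T, axis=1)
    scale = float(norms.mean())
    W = W / scale
    norms = norms / scale
    cv = float(norms.std() / norms.mean())
    return CalibrationModel(offset=b, matrix=W, field_magnitude=float(norms.mean()), fit_cv=cv)


def apply_calibration(
    table: SensorTable,
    model: CalibrationModel,
    suffix: str = "_cal",
) -> SensorTable:
    """Append corrected magnetometer channels (``mx_cal`` etc.) to a table.

    Nulls in the raw channels propagate to the corrected ones.
    """
    try:
        names = table.schema.triad("mag")
    except KeyError as exc:
        raise ValueError("table has no mag-x/y/z channels to calibrate") from exc
    corrected = model.apply(table.triad("mag"))
    cols = {f"{n}{suffix}": corrected[:, i] for i, n in enumerate(names)}
    return table.with_columns(cols)


def save_model(model: CalibrationModel, path) -> None:
    """Serialise the model as labelled, human-editable plain text."""
    with open(path, "w") as fh:
        fh.write("# magnetometer calibration: corrected = W (x - b)\n")
        fh.write("offset_b: " + " ".join(repr(float(v)) for v in model.offset) + "\n")
        for i in range(3):
            fh.write(f"W_row{i}: " + " ".join(repr(float(v)) for v in model.matrix[i]) + "\n")
        fh.write(f"field_magnitude: {float(model.field_magnitude)!r}\n")
        fh.write(f"fit_cv: {float(model.fit_cv)!r}\n")


def load_model(path) -> CalibrationModel:
    """Load a model written by :func:`save_model` (lossless round trip)."""
    values: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            values[key.strip()] = [float(tok) for tok in rest.split()]
    try:
        b = np.array(values["offset_b"], dtype=float)
        W = np.array([values[f"W_row{i}"] for i in range(3)], dtype=float)
        mag = values.get("field_magnitude", [1.0])[0]
        cv = values.get("fit_cv", [0.0])[0]
    except (KeyError, IndexError) as exc:
        raise ValueError(f"malformed calibration file {path!r}: missing {exc}") from exc
    if b.shape != (3,) or W.shape != (3, 3):
        raise ValueError(f"malformed calibration file {path!r}: wrong shapes")
    return CalibrationModel(offset=b, matrix=W, field_magnitude=mag, fit_cv=cv)
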