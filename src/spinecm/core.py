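"""Raw scan representation, speed-invariant normalization, and curve reconstruction.

A continuous trunk scan is a sequence of timestamped inclination angles
recorded while an inclinometer (a smartphone in a rigid holder) is slid
along the spine from C7 to S1.  Because the operator's hand speed varies,
raw recordings are not comparable across acquisitions.  The pipeline here
turns a raw trace into a fixed-length, speed-independent angular profile
("chunk averaging" to 400 points) and reconstructs a smooth curve from it
by degree-9 polynomial regression, the representation from which clinical
landmarks are extracted downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from numpy.polynomial import polynomial as _poly

__all__ = [
    "Plane",
    "Posture",
    "AngularTrace",
    "NormalizedProfile",
    "PolynomialFit",
    "InvalidTraceError",
    "UnderdeterminedFitError",
    "normalize_profile",
    "fit_polynomial",
    "evaluate_derivative",
]

DEFAULT_N_POINTS = 400
DEFAULT_DEGREE = 9


class Plane(str, enum.Enum):
    """Measurement plane: transverse (trunk rotation) or sagittal (inclination)."""

    TRANSVERSE = "transverse"
    SAGITTAL = "sagittal"


class Posture(str, enum.Enum):
    """Patient posture during the scan: Adams forward bend or upright standing."""

    ADAMS = "adams"
    STANDING = "standing"


class InvalidTraceError(ValueError):
    """Raised when a raw trace violates its structural invariants."""


class UnderdeterminedFitError(ValueError):
    """Raised when the polynomial degree is too high for the profile length."""


@dataclass(frozen=True)
class AngularTrace:
    """One raw continuous scan: timestamped angles plus acquisition metadata.

    Parameters
    ----------
    t : array of float
        Sample timestamps in seconds, strictly increasing.
    angle : array of float
        Angles in degrees, finite, |angle| <= 180.
    plane, posture : Plane, Posture
        Acquisition plane and patient posture.
    device_rate_hint : float, optional
        Nominal device sampling rate in Hz (informational only).
    calibration_offset : float
        Operator-defined zero offset in degrees, subtracted before any
        processing.
    """

    t: np.ndarray
    angle: np.ndarray
    plane: Plane
    posture: Posture
    device_rate_hint: float | None = None
    calibration_offset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "angle", a)
        object.__setattr__(self, "plane", Plane(self.plane))
        object.__setattr__(self, "posture", Posture(self.posture))
        if t.ndim != 1 or a.ndim != 1 or t.shape != a.shape:
            raise InvalidTraceError("t and angle must be 1-D arrays of equal length")
        if len(t) < 2:
            raise InvalidTraceError("a trace requires at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidTraceError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(t)):
            raise InvalidTraceError("samples must be finite")
        if np.any(np.abs(a) > 180.0):
            raise InvalidTraceError("angles must satisfy |angle| <= 180 degrees")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class NormalizedProfile:
    """Fixed-length speed-invariant angular profile over normalized arc position.

    Arc position runs over [0, 1] with 0 at the C7 end and 1 at the S1 end;
    value ``i`` sits at the chunk midpoint ``s_i = (i + 0.5) / n_points``.
    """

    values: np.ndarray
    plane: Plane
    posture: Posture

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "plane", Plane(self.plane))
        object.__setattr__(self, "posture", Posture(self.posture))
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("profile must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")

    @property
    def n_points(self) -> int:
        return len(self.values)

    @property
    def arc_positions(self) -> np.ndarray:
        n = self.n_points
        return (np.arange(n) + 0.5) / n


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial reconstruction of a normalized profile.

    ``coefficients`` are in the monomial basis over arc position s in [0, 1],
    ascending order (length ``degree + 1``).  ``fitted_values`` is the
    polynomial evaluated at ``arc_positions``.
    """

    degree: int
    coefficients: np.ndarray
    arc_positions: np.ndarray
    fitted_values: np.ndarray
    residual_rms: float
    plane: Plane = Plane.TRANSVERSE
    posture: Posture = Posture.ADAMS

    def __call__(self, s) -> np.ndarray:
        return _poly.polyval(np.asarray(s, dtype=float), self.coefficients)


def normalize_profile(trace: AngularTrace, n_points: int = DEFAULT_N_POINTS) -> NormalizedProfile:
    """Resample a raw scan into a fixed-length, speed-independent profile.

    The calibration offset is subtracted, then the sample sequence is
    partitioned into ``n_points`` consecutive index chunks (chunk ``i``
    spans raw indices ``[floor(i*N/n), floor((i+1)*N/n))``) and each chunk
    is replaced by its mean.  If the trace holds fewer than ``n_points``
    samples it is first linearly interpolated in index space up to exactly
    ``n_points``.  No filtering is applied; noise suppression is left to
    the downstream polynomial fit.
    """
    if not isinstance(trace, AngularTrace):
        raise InvalidTraceError("expected an AngularTrace")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    angles = trace.angle - trace.calibration_offset
    n_raw = len(angles)
    if n_raw < n_points:
        idx = np.linspace(0.0, n_raw - 1.0, n_points)
        angles = np.interp(idx, np.arange(n_raw), angles)
        n_raw = n_points

    edges = (np.arange(n_points + 1, dtype=np.int64) * n_raw) // n_points
    counts = np.diff(edges)
    # per-chunk summation keeps single-sample chunks bit-exact
    values = np.add.reduceat(angles, edges[:-1]) / counts
    return NormalizedProfile(values=values, plane=trace.plane, posture=trace.posture)


def fit_polynomial(profile: NormalizedProfile, degree: int = DEFAULT_DEGREE) -> PolynomialFit:
    """Fit a degree-``degree`` polynomial to the profile by least squares.

    The regression is performed in a Chebyshev basis on the data domain for
    numerical conditioning and converted to monomial coefficients over
    s in [0, 1].  A degree-9 fit is flexible enough for multi-inversion
    spinal profiles while still smoothing sample noise.
    """
    s = profile.arc_positions
    y = profile.values
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if degree + 1 > len(y):
        raise UnderdeterminedFitError(
            f"degree {degree} fit needs at least {degree + 1} points, got {len(y)}"
        )
    cfit = _cheb.Chebyshev.fit(s, y, degree)
    coefficients = cfit.convert(kind=_poly.Polynomial).coef
    # convert() can drop trailing near-zero terms; pad back to full length
    if len(coefficients) < degree + 1:
        coefficients = np.concatenate(
            [coefficients, np.zeros(degree + 1 - len(coefficients))]
        )
    fitted = _poly.polyval(s, coefficients)
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return PolynomialFit(
        degree=degree,
        coefficients=coefficients,
        arc_positions=s,
        fitted_values=fitted,
        residual_rms=rms,
        plane=profile.plane,
        posture=profile.posture,
    )


def evaluate_derivative(fit: PolynomialFit, order: int = 1) -> np.ndarray:
    """Analytic derivative of the fitted polynomial at the profile arc positions.

    Only first and second derivatives are supported; they are what landmark
    localization uses (extrema and curvature).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dcoef = _poly.polyder(fit.coefficients, m=order)
    return _poly.polyval(fit.arc_positions, dcoef)
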