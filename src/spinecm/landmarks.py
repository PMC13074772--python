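"""Turning-point detection and clinical parameter extraction.

The reconstructed scan curve is summarized by three key turning points:
the global valley ``n2`` and the nearest local peaks to its left (``n1``)
and right (``n3``), with deterministic edge fallbacks.  From these the
clinical outcomes are derived: the angle of trunk rotation (ATR) in the
transverse plane, and thoracic kyphosis / lumbar lordosis amplitudes in
the sagittal plane (``var1 = n1 - n2``, ``var2 = n2 - n3``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Plane, PolynomialFit, Posture, evaluate_derivative

__all__ = [
    "Landmark",
    "LandmarkSet",
    "ClinicalOutcome",
    "detect_landmarks",
    "derive_variables",
    "extract_transverse",
    "extract_sagittal",
    "round_half_away",
]


@dataclass(frozen=True)
class Landmark:
    """A single turning point: index into the series and the value there."""

    index: int
    value: float


@dataclass(frozen=True)
class LandmarkSet:
    """The n1/n2/n3 turning points of one series.

    ``source`` records whether the series was the polynomial reconstruction
    ("poli") or the raw normalized profile ("orig").
    """

    n1: Landmark
    n2: Landmark
    n3: Landmark
    source: str = "poli"

    def __post_init__(self) -> None:
        if not (self.n1.index <= self.n2.index <= self.n3.index):
            raise ValueError("landmark indices must be ordered n1 <= n2 <= n3")


@dataclass(frozen=True)
class ClinicalOutcome:
    """Clinical parameters extracted from one reconstructed scan.

    Transverse scans populate ``atr`` (integer degrees, scoliometer
    convention), the signed hump extrema and their arc positions; sagittal
    scans populate kyphosis/lordosis amplitudes, the apex and transition
    arc positions.  ``var1``/``var2`` carry the standardized per-posture
    variables in every case.
    """

    plane: Plane
    posture: Posture
    var1: float
    var2: float
    landmarks_poli: LandmarkSet
    landmarks_orig: LandmarkSet | None = None
    atr: int | None = None
    hump_right: float | None = None
    hump_left: float | None = None
    hump_right_apex_s: float | None = None
    hump_left_apex_s: float | None = None
    kyphosis: float | None = None
    lordosis: float | None = None
    kyphosis_apex_s: float | None = None
    lordosis_apex_s: float | None = None
    transition_s: float | None = None
    degenerate: bool = False


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Matches scoliometer reporting at 1 degree resolution and is symmetric
    for left- and right-sided humps.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _compress_plateaus(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to their first index."""
    keep = np.concatenate(([True], np.diff(x) != 0))
    idx = np.flatnonzero(keep)
    return idx, x[idx]


def detect_landmarks(series, source: str = "poli") -> LandmarkSet:
    """Locate the n1/n2/n3 turning points of a 1-D series.

    ``n2`` is the global minimum (first occurrence on ties).  ``n1`` is the
    nearest local peak strictly left of ``n2``; if no peak exists it falls
    back to the maximum over the left segment, and if ``n2`` sits at the
    left edge then ``n1 = n2``.  ``n3`` follows the mirror rule on the
    right.  Plateaus (runs of equal values) are treated as a single
    candidate at their first index, so a flat series yields
    ``n1 = n2 = n3`` at index 0.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("series values must be finite")

    idx, v = _compress_plateaus(x)
    m = len(v)
    j2 = int(np.argmin(v))
    n2 = Landmark(int(idx[j2]), float(v[j2]))

    def is_peak(j: int) -> bool:
        return 0 < j < m - 1 and v[j] > v[j - 1] and v[j] > v[j + 1]

    # n1: nearest peak scanning leftward from n2, else left-segment maximum,
    # else n2 itself when the minimum is at the left edge.
    if j2 == 0:
        n1 = n2
    else:
        j = next((jj for jj in range(j2 - 1, 0, -1) if is_peak(jj)), None)
        if j is None:
            j = int(np.argmax(v[:j2]))
        n1 = Landmark(int(idx[j]), float(v[j]))

    if j2 == m - 1:
        n3 = n2
    else:
        j = next((jj for jj in range(j2 + 1, m - 1) if is_peak(jj)), None)
        if j is None:
            j = j2 + 1 + int(np.argmax(v[j2 + 1 :]))
        n3 = Landmark(int(idx[j]), float(v[j]))

    return LandmarkSet(n1=n1, n2=n2, n3=n3, source=source)


def derive_variables(landmarks: LandmarkSet, plane: Plane, posture: Posture) -> tuple[float, float]:
    """Derive the standardized variables var1/var2 from a landmark set.

    Transverse acquisitions (Adams forward bend and standing rib hump) use
    the landmark values directly: ``var1 = n1``, ``var2 = n2``.  The
    sagittal standing acquisition uses successive differences, i.e. the
    relative amplitudes between turning points: ``var1 = n1 - n2`` and
    ``var2 = n2 - n3``.
    """
    plane = Plane(plane)
    Posture(posture)
    if plane is Plane.TRANSVERSE:
        return landmarks.n1.value, landmarks.n2.value
    return (
        landmarks.n1.value - landmarks.n2.value,
        landmarks.n2.value - landmarks.n3.value,
    )


def _derivative_zero_nearest(fit: PolynomialFit, s_target: float) -> float:
    """Arc position of the first-derivative zero crossing nearest s_target.

    Zero crossings are located on the fitted grid with linear interpolation;
    if the derivative never changes sign the target position is returned
    unchanged.
    """
    s = fit.arc_positions
    d1 = evaluate_derivative(fit, 1)
    sign = np.sign(d1)
    flips = np.flatnonzero(np.diff(sign) != 0)
    if len(flips) == 0:
        return float(s_target)
    crossings = []
    for i in flips:
        d0, d1v = d1[i], d1[i + 1]
        if d1v == d0:
            crossings.append(0.5 * (s[i] + s[i + 1]))
        else:
            w = d0 / (d0 - d1v)
            crossings.append(s[i] + w * (s[i + 1] - s[i]))
    crossings = np.asarray(crossings)
    return float(crossings[np.argmin(np.abs(crossings - s_target))])


def extract_transverse(
    fit: PolynomialFit, profile_values=None, posture: Posture | None = None
) -> ClinicalOutcome:
    """Extract transverse-plane outcomes (ATR, hump extrema) from a fit.

    The right-sided hump is the signed global maximum of the reconstructed
    curve (reported when positive), the left-sided hump the signed global
    minimum (reported when negative).  The ATR is the absolute magnitude of
    the most prominent of the two, rounded half-away-from-zero to a whole
    degree; ties favor the right side.
    """
    y = fit.fitted_values
    s = fit.arc_positions
    imax = int(np.argmax(y))
    imin = int(np.argmin(y))
    vmax = float(y[imax])
    vmin = float(y[imin])

    hump_right = vmax if vmax > 0 else 0.0
    hump_left = vmin if vmin < 0 else 0.0
    prominent = hump_right if hump_right >= -hump_left else hump_left
    atr = abs(round_half_away(prominent))

    lm_poli = detect_landmarks(y, source="poli")
    lm_orig = (
        detect_landmarks(np.asarray(profile_values, dtype=float), source="orig")
        if profile_values is not None
        else None
    )
    return ClinicalOutcome(
        plane=Plane.TRANSVERSE,
        posture=Posture(posture) if posture is not None else fit.posture,
        var1=vmax,
        var2=vmin,
        landmarks_poli=lm_poli,
        landmarks_orig=lm_orig,
        atr=atr,
        hump_right=hump_right,
        hump_left=hump_left,
        hump_right_apex_s=float(s[imax]) if hump_right > 0 else None,
        hump_left_apex_s=float(s[imin]) if hump_left < 0 else None,
    )


def extract_sagittal(fit: PolynomialFit, profile_values=None) -> ClinicalOutcome:
    """Extract sagittal-plane outcomes (kyphosis, lordosis, apices) from a fit.

    Landmarks are detected on the reconstructed curve; the thoracic
    kyphosis amplitude is ``var1 = n1 - n2`` and the lumbar lordosis
    amplitude ``var2 = n2 - n3``.  Apex arc positions are taken from the
    first-derivative zeros nearest n1 and n3; the thoracolumbar transition
    is placed at n2.  A scan whose valley lands on an edge of the series
    has no interior minimum; its landmarks follow the edge fallbacks and
    the outcome is flagged degenerate.
    """
    y = fit.fitted_values
    s = fit.arc_positions
    lm = detect_landmarks(y, source="poli")
    var1, var2 = derive_variables(lm, Plane.SAGITTAL, Posture.STANDING)

    last = len(y) - 1
    degenerate = lm.n2.index == 0 or lm.n2.index >= last or np.ptp(y) == 0

    lm_orig = (
        detect_landmarks(np.asarray(profile_values, dtype=float), source="orig")
        if profile_values is not None
        else None
    )
    return ClinicalOutcome(
        plane=Plane.SAGITTAL,
        posture=Posture.STANDING,
        var1=var1,
        var2=var2,
        landmarks_poli=lm,
        landmarks_orig=lm_orig,
        kyphosis=var1,
        lordosis=var2,
        kyphosis_apex_s=_derivative_zero_nearest(fit, float(s[lm.n1.index])),
        lordosis_apex_s=_derivative_zero_nearest(fit, float(s[lm.n3.index])),
        transition_s=float(s[lm.n2.index]),
        degenerate=bool(degenerate),
    )
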