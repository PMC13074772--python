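"""Synthetic back-scan and rater-agreement data with known ground truth.

Real scans are continuous angle traces recorded while sliding an
inclinometer along the back of an adolescent with a spinal deformity.
This module emulates them: a smooth spine-shaped angular field (a sum of
Gaussian bumps, able to produce single/double rib humps and
kyphotic-then-lordotic sagittal curves), sampled under a variable operator
speed profile, at device rates near 10 Hz (transverse) or 100 Hz
(sagittal), with timing jitter and Gaussian angle noise.  It also
generates subjects x raters measurement tables from a two-way additive
model with controllable population ICC, so every statistic in the
agreement module can be exercised against known truth.

All randomness is driven by explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .agreement import RatingTable
from .core import AngularTrace, Plane, Posture

__all__ = [
    "SpineBump",
    "SpineGeometry",
    "ScanConfig",
    "ReliabilityDesign",
    "evaluate_geometry",
    "scan",
    "simulate_rating_table",
    "error_sd_for_target_icc",
    "transverse_geometry",
    "sagittal_geometry_from_landmarks",
    "MEASURE_PRESETS",
    "reliability_design_for_measure",
]


@dataclass(frozen=True)
class SpineBump:
    """One localized angular feature: amplitude (deg), center and width (arc)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.center <= 1.0):
            raise ValueError("bump center must lie in [0, 1]")
        if self.width <= 0:
            raise ValueError("bump width must be positive")


@dataclass(frozen=True)
class SpineGeometry:
    """Smooth angular field g(s) over arc position s in [0, 1].

    g(s) = baseline + sum_j amplitude_j * exp(-(s - center_j)^2 / (2 width_j^2)).
    """

    plane: Plane
    components: tuple[SpineBump, ...] = ()
    baseline: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plane", Plane(self.plane))
        object.__setattr__(self, "components", tuple(self.components))

    def __call__(self, s):
        return evaluate_geometry(self, s)


def evaluate_geometry(geom: SpineGeometry, s):
    """Evaluate the angular field at arc position(s) s in [0, 1]."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0.0) or np.any(s_arr > 1.0):
        raise ValueError("arc position must lie in [0, 1]")
    out = np.full_like(s_arr, geom.baseline, dtype=float)
    for b in geom.components:
        out = out + b.amplitude * np.exp(-((s_arr - b.center) ** 2) / (2.0 * b.width**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition model for one synthetic scan.

    ``speed_profile`` controls the operator hand-speed time-warp s(t):

    * ``uniform`` - constant speed;
    * ``sinusoidal`` - speed proportional to 1 + a sin(2 pi f t) with
      ``speed_amplitude`` a (|a| < 1) and ``speed_freq_hz`` f, an
      oscillating push-pause pattern;
    * ``random_walk`` - speed follows an exponentiated Gaussian random
      walk (always positive), a drifting irregular pace.

    The warp is normalized so s(0) = 0 and s(t_end) = 1 (a whole-spine
    C7-to-S1 pass).  ``noise_sd`` is Gaussian angle noise in degrees;
    ``timing_jitter_sd`` perturbs inter-sample intervals in seconds.  The
    calibration offset is added to the emitted samples and recorded in the
    trace metadata, mirroring the operator zeroing step that downstream
    normalization undoes.
    """

    duration: float = 10.0
    rate: float = 10.0
    speed_profile: str = "uniform"
    speed_amplitude: float = 0.3
    speed_freq_hz: float = 2.0
    speed_walk_sd: float = 0.02
    noise_sd: float = 0.0
    timing_jitter_sd: float = 0.0
    calibration_offset: float = 0.0
    posture: Posture = Posture.ADAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if self.noise_sd < 0 or self.timing_jitter_sd < 0:
            raise ValueError("noise and jitter SDs must be non-negative")
        if self.speed_profile not in ("uniform", "sinusoidal", "random_walk"):
            raise ValueError("unknown speed profile")
        if self.speed_profile == "sinusoidal" and not abs(self.speed_amplitude) < 1:
            raise ValueError("sinusoidal speed amplitude must satisfy |a| < 1")
        object.__setattr__(self, "posture", Posture(self.posture))


def scan(geom: SpineGeometry, cfg: ScanConfig) -> AngularTrace:
    """Simulate one continuous scan of a geometry under an acquisition config.

    Sample times are laid at nominal spacing 1/rate plus jitter; the speed
    profile maps time to arc position; angles are g(s(t)) plus the
    calibration offset plus Gaussian noise.  Deterministic for a fixed
    seed (jitter, speed walk and noise are drawn in that fixed order).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.rate)) + 1
    if n < 2:
        raise ValueError("config yields fewer than 2 samples")

    dts = np.full(n - 1, 1.0 / cfg.rate)
    if cfg.timing_jitter_sd > 0:
        dts = dts + rng.normal(0.0, cfg.timing_jitter_sd, n - 1)
        dts = np.maximum(dts, 0.1 / cfg.rate)  # keep timestamps strictly increasing
    t = np.concatenate(([0.0], np.cumsum(dts)))

    if cfg.speed_profile == "uniform":
        u = t.copy()
    elif cfg.speed_profile == "sinusoidal":
        a, f = cfg.speed_amplitude, cfg.speed_freq_hz
        u = t + a * (1.0 - np.cos(2.0 * math.pi * f * t)) / (2.0 * math.pi * f)
    else:  # random_walk
        walk = np.cumsum(rng.normal(0.0, cfg.speed_walk_sd, n - 1))
        speeds = np.exp(walk)
        u = np.concatenate(([0.0], np.cumsum(dts * speeds)))

    if not np.all(np.diff(u) > 0):
        raise ValueError("speed profile induced a non-increasing time-warp")
    s = u / u[-1]
    s[0], s[-1] = 0.0, 1.0

    angles = evaluate_geometry(geom, s) + cfg.calibration_offset
    if cfg.noise_sd > 0:
        angles = angles + rng.normal(0.0, cfg.noise_sd, n)

    return AngularTrace(
        t=t,
        angle=angles,
        plane=geom.plane,
        posture=cfg.posture,
        device_rate_hint=cfg.rate,
        calibration_offset=cfg.calibration_offset,
    )


@dataclass(frozen=True)
class ReliabilityDesign:
    """Two-way additive model for a subjects x measurements table.

    Observation (i, j) = true_i + rater_bias_j + e_ij with
    true_i ~ N(subject_mean, subject_sd^2) and e_ij ~ N(0, error_sd^2).
    Rater biases are fixed per-column offsets.
    """

    n_subjects: int
    k_measurements: int = 2
    subject_mean: float = 0.0
    subject_sd: float = 1.0
    error_sd: float = 1.0
    rater_biases: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_measurements < 2:
            raise ValueError("need >= 2 subjects and >= 2 measurements")
        if self.subject_sd < 0 or self.error_sd < 0:
            raise ValueError("SDs must be non-negative")
        biases = tuple(self.rater_biases) or (0.0,) * self.k_measurements
        if len(biases) != self.k_measurements:
            raise ValueError("need one rater bias per measurement column")
        object.__setattr__(self, "rater_biases", biases)

    @property
    def population_icc(self) -> float:
        """Implied absolute-agreement average-measures ICC of the design."""
        bias_var = float(np.var(self.rater_biases, ddof=1)) if self.k_measurements > 1 else 0.0
        s2 = self.subject_sd**2
        denom = s2 + (bias_var + self.error_sd**2) / self.k_measurements
        return float("nan") if denom == 0 else s2 / denom


def simulate_rating_table(design: ReliabilityDesign) -> RatingTable:
    """Draw one subjects x measurements table from a reliability design."""
    rng = np.random.default_rng(design.seed)
    true = rng.normal(design.subject_mean, design.subject_sd, design.n_subjects)
    noise = rng.normal(0.0, design.error_sd, (design.n_subjects, design.k_measurements))
    values = true[:, None] + np.asarray(design.rater_biases)[None, :] + noise
    return RatingTable(values=values)


def error_sd_for_target_icc(target_icc: float, subject_sd: float, k: int) -> float:
    """Residual SD giving a target average-measures ICC with zero rater bias.

    Inverts subject_sd^2 / (subject_sd^2 + error_sd^2 / k) = target_icc.
    """
    if not (0.0 < target_icc < 1.0):
        raise ValueError("target_icc must lie strictly in (0, 1)")
    if subject_sd <= 0:
        raise ValueError("subject_sd must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    return subject_sd * math.sqrt(k * (1.0 - target_icc) / target_icc)


def transverse_geometry(
    amplitude: float = 8.0,
    side: str = "right",
    center: float = 0.4,
    width: float = 0.15,
    baseline: float = 0.0,
) -> SpineGeometry:
    """Single rib-hump transverse geometry; positive = right-sided convexity.

    The default width (0.15 of the C7-S1 arc) corresponds to a hump
    spanning several vertebral levels and is wide enough for a degree-9
    polynomial to track the bump with sub-degree error.
    """
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    signed = amplitude if side == "right" else -amplitude
    return SpineGeometry(
        plane=Plane.TRANSVERSE,
        components=(SpineBump(signed, center, width),),
        baseline=baseline,
    )


def sagittal_geometry_from_landmarks(
    n1: float = 12.0,
    n2: float = -18.5,
    n3: float = 24.7,
    centers: tuple[float, float, float] = (0.2, 0.55, 0.9),
    width: float = 0.16,
    baseline: float = 0.0,
    refine: int = 3,
) -> SpineGeometry:
    """Sagittal geometry whose turning points hit prescribed n1/n2/n3 values.

    Builds a three-bump field (kyphotic peak, thoracolumbar valley,
    lordotic/sacral peak) and solves for the bump amplitudes so that the
    field's actual extremum values equal the targets.  Because
    neighbouring bumps overlap, the extremum locations shift slightly off
    the bump centers; a few fixed-point refinements on a dense grid pin
    the values down to well below 0.01 degrees.

    The defaults reproduce a typical adolescent sagittal profile with a
    thoracic kyphosis amplitude n1 - n2 = 30.5 deg and a lumbar lordosis
    amplitude n2 - n3 = -43.2 deg.
    """
    targets = np.array([n1, n2, n3], dtype=float) - baseline
    if not (targets[1] < targets[0] and targets[1] < targets[2]):
        raise ValueError("n2 must be below both n1 and n3")
    c = np.asarray(centers, dtype=float)
    locs = c.copy()
    grid = np.linspace(0.0, 1.0, 4001)
    amps = targets.copy()
    for _ in range(max(1, refine)):
        basis = np.exp(-((locs[:, None] - c[None, :]) ** 2) / (2.0 * width**2))
        amps = np.linalg.solve(basis, targets)
        field = baseline + np.exp(
            -((grid[:, None] - c[None, :]) ** 2) / (2.0 * width**2)
        ) @ amps
        # re-locate the three extrema between the midpoints of the centers
        mid01 = 0.5 * (c[0] + c[1])
        mid12 = 0.5 * (c[1] + c[2])
        seg0 = grid <= mid01
        seg1 = (grid > mid01) & (grid <= mid12)
        seg2 = grid > mid12
        locs = np.array(
            [
                grid[seg0][np.argmax(field[seg0])],
                grid[seg1][np.argmin(field[seg1])],
                grid[seg2][np.argmax(field[seg2])],
            ]
        )
    bumps = tuple(SpineBump(float(a), float(ci), width) for a, ci in zip(amps, c))
    return SpineGeometry(plane=Plane.SAGITTAL, components=bumps, baseline=baseline)


# Desk-scale presets mirroring the magnitudes of typical intrarater
# reliability tables for this instrument: per-measure population mean, SD
# and target ICC used to parameterize ReliabilityDesign objects.
MEASURE_PRESETS: dict[str, dict[str, float]] = {
    "right_adams": {"mean": 4.8, "sd": 4.1, "icc": 0.93},
    "left_adams": {"mean": -4.7, "sd": 4.0, "icc": 0.56},
    "right_standing": {"mean": 2.6, "sd": 1.9, "icc": 0.60},
    "left_standing": {"mean": -5.0, "sd": 3.0, "icc": 0.69},
    "kyphosis": {"mean": 30.5, "sd": 12.9, "icc": 0.54},
    "lordosis": {"mean": -43.2, "sd": 7.8, "icc": 0.77},
}


def reliability_design_for_measure(
    measure: str,
    n_subjects: int = 32,
    k_measurements: int = 2,
    seed: int = 0,
) -> ReliabilityDesign:
    """Reliability design calibrated to a named measure preset.

    The subject SD is taken from the preset and the residual SD is solved
    so the design's population absolute-agreement average-measures ICC
    equals the preset ICC (zero rater bias).
    """
    p = MEASURE_PRESETS[measure]
    err = error_sd_for_target_icc(p["icc"], p["sd"], k_measurements)
    return ReliabilityDesign(
        n_subjects=n_subjects,
        k_measurements=k_measurements,
        subject_mean=p["mean"],
        subject_sd=p["sd"],
        error_sd=err,
        seed=seed,
    )
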