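"""End-to-end runs: trace -> profile -> fit -> clinical report, and the
statistical analyses on measurement tables."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .agreement import (
    AgreementEstimate,
    ValidityReport,
    icc_absolute_agreement,
    validity_report,
)
from .core import (
    DEFAULT_DEGREE,
    DEFAULT_N_POINTS,
    Plane,
    fit_polynomial,
    normalize_profile,
)
from .landmarks import ClinicalOutcome, extract_sagittal, extract_transverse

__all__ = ["RunConfig", "extract_outcome", "run_extract", "run_agree", "run_validate"]

logger = logging.getLogger("spinecm")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; the defaults are the instrument's standard
    constants (400-point profile, degree-9 fit, alpha = 0.05, z = 1.96)."""

    n_points: int = DEFAULT_N_POINTS
    degree: int = DEFAULT_DEGREE
    z: float = 1.96
    alpha: float = 0.05
    seed: int | None = None


def extract_outcome(trace, config: RunConfig = RunConfig()) -> ClinicalOutcome:
    """Full single-scan pipeline: normalize, fit, extract landmarks/outcomes."""
    profile = normalize_profile(trace, n_points=config.n_points)
    fit = fit_polynomial(profile, degree=config.degree)
    if profile.plane is Plane.TRANSVERSE:
        return extract_transverse(fit, profile_values=profile.values, posture=profile.posture)
    return extract_sagittal(fit, profile_values=profile.values)


def run_extract(trace_paths, out_dir, config: RunConfig = RunConfig()) -> dict:
    """Process a batch of trace files into clinical outcome JSON reports.

    Each trace gets ``<stem>.outcome.json`` in ``out_dir``; malformed
    files are reported per-file without aborting the batch.  Returns a
    summary with per-file status and counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results, errors = [], []
    for p in map(Path, trace_paths):
        try:
            trace, meta = _io.read_trace(p)
            logger.info("extract: %s (%d samples, %s/%s)", p, len(trace),
                        trace.plane.value, trace.posture.value)
            outcome = extract_outcome(trace, config)
            report = _io.outcome_to_dict(outcome)
            report["source"] = str(p)
            report["metadata"] = meta
            out_path = out_dir / (p.stem + ".outcome.json")
            _io.write_json_report(out_path, report)
            results.append({"file": str(p), "report": str(out_path)})
        except Exception as exc:  # noqa: BLE001 - per-file error reporting
            logger.error("extract failed for %s: %s", p, exc)
            errors.append({"file": str(p), "error": str(exc)})
    return {"n_ok": len(results), "n_failed": len(errors), "results": results, "errors": errors}


def run_agree(table_path, config: RunConfig = RunConfig(), consistency: bool = False) -> dict:
    """ICC/SEM/MDC reproducibility report for a rating-table CSV."""
    table = _io.read_rating_table(table_path)
    est = icc_absolute_agreement(
        table, consistency=consistency, alpha=config.alpha, z=config.z
    )
    report = dataclasses.asdict(est)
    report["source"] = str(table_path)
    report["subjects"] = list(table.subject_ids)
    report["measurements"] = list(table.columns)
    return report


def run_validate(table_path, config: RunConfig = RunConfig()) -> dict:
    """Concurrent-validity report for a paired two-column CSV.

    The first measurement column is the candidate method, the second the
    reference (e.g. scoliometer).
    """
    table = _io.read_rating_table(table_path)
    if table.n_measurements != 2:
        raise ValueError("validation requires exactly 2 measurement columns")
    x, y = table.values[:, 0], table.values[:, 1]
    rep = validity_report(x, y, z=config.z)
    report = dataclasses.asdict(rep)
    report["source"] = str(table_path)
    report["method_column"] = table.columns[0]
    report["reference_column"] = table.columns[1]
    return report
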