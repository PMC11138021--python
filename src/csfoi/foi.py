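"""The Fluid Oscillation Index (FOI) and the f-to-VA exponential estimator.

4D-flow MRI measures CSF velocity amplitude (VA, cm/s) only at a handful of
midline regions, while the IVIM perfusion fraction ``f`` (%) is available
throughout the intracranial CSF space.  Across regions where both exist the
two are related by an exponential calibration curve

    VA_est(f) = exp(a * (f - b)) + c        (a = 0.2 /%, b = 85 %, c = 0.25 cm/s)

which crosses ~0.4 cm/s at f = 75%: below that, f is the more informative
oscillation measure; above it, VA is.  The two are merged into a single
weighted index

    FOI = VA * 10 + f * 0.02

using the measured VA where 4D flow covers the region and the estimated VA
elsewhere.  This module implements the estimator, the least-squares
calibration fit that produces it, the index itself, and the assembly of a
45-region FOI table (with the flow-to-IVIM ROI name mapping, including the
lower-aqueduct / upper-fourth-ventricle equivalence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .ivim import ROIFStats

__all__ = [
    "VAFCurve",
    "FOIRecord",
    "DEFAULT_CURVE",
    "roi_vocabulary",
    "estimate_va",
    "fit_va_curve",
    "compute_foi",
    "foi_table",
]

# FOI weighting constants; the published index uses these verbatim.
VA_WEIGHT = 10.0
F_WEIGHT = 0.02


@dataclass(frozen=True)
class VAFCurve:
    """Exponential f (%) -> VA (cm/s) calibration: exp(a*(f - b)) + c."""

    a: float = 0.2
    b: float = 85.0
    c: float = 0.25

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("rate a must be positive")
        if self.c < 0:
            raise ValueError("offset c must be nonnegative")

    def __call__(self, f_percent: float | np.ndarray) -> float | np.ndarray:
        return estimate_va(f_percent, self)


DEFAULT_CURVE = VAFCurve()


@dataclass(frozen=True)
class FOIRecord:
    """One region's fluid oscillation index with VA provenance."""

    roi_name: str
    f_percent: float
    va_cm_s: float
    va_source: str  # "measured" | "estimated"
    foi: float


def roi_vocabulary() -> dict:
    """The packaged ROI vocabulary: 45 IVIM regions, 7 flow regions, and the
    flow-to-IVIM name mapping."""
    text = (
        importlib_resources.files("csfoi.resources")
        .joinpath("roi_vocabulary.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)


def estimate_va(
    f_percent: float | np.ndarray, curve: VAFCurve = DEFAULT_CURVE
) -> float | np.ndarray:
    """Estimated velocity amplitude exp(a*(f - b)) + c in cm/s.

    Strictly increasing in ``f_percent``, which must lie in [0, 100].
    """
    f = np.asarray(f_percent, dtype=float)
    if np.any(f < 0) or np.any(f > 100):
        raise ValueError("f_percent must lie in [0, 100]")
    out = np.exp(curve.a * (f - curve.b)) + curve.c
    return float(out) if out.ndim == 0 else out


def fit_va_curve(
    pairs: Sequence[tuple[float, float]],
    fix_shift: float = 85.0,
) -> tuple[VAFCurve, float]:
    """Least-squares fit of the exponential calibration to (f %, VA cm/s) pairs.

    The shift ``b`` is held fixed (default 85): exp(a*(f-b)) confounds b with
    an overall scale, so only the rate ``a`` and offset ``c`` are free.
    Returns the fitted curve and the residual sum of squares.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (f, va) pairs")
    f, va = arr[:, 0], arr[:, 1]
    if np.unique(f).size < 2:
        raise ValueError("all f values identical: curve is unidentifiable")

    def residuals(x: np.ndarray) -> np.ndarray:
        a, c = x
        return np.exp(a * (f - fix_shift)) + c - va

    result = least_squares(
        residuals, x0=np.array([0.1, 0.1]),
        bounds=(np.array([1e-6, 0.0]), np.array([5.0, np.inf])),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a_hat, c_hat = result.x
    curve = VAFCurve(a=float(a_hat), b=float(fix_shift), c=float(c_hat))
    return curve, float(2.0 * result.cost)


def compute_foi(
    f_percent: float,
    va_cm_s: float | None = None,
    roi_name: str = "",
    curve: VAFCurve = DEFAULT_CURVE,
) -> FOIRecord:
    """FOI = VA * 10 + f * 0.02, preferring measured VA when available.

    When ``va_cm_s`` is None the VA is estimated from ``f_percent`` via the
    calibration curve and the record is tagged ``va_source="estimated"``.
    """
    if not 0 <= f_percent <= 100:
        raise ValueError("f_percent must lie in [0, 100]")
    if va_cm_s is not None:
        if va_cm_s < 0:
            raise ValueError("measured va_cm_s must be nonnegative")
        va, source = float(va_cm_s), "measured"
    else:
        va, source = float(estimate_va(f_percent, curve)), "estimated"
    return FOIRecord(
        roi_name=roi_name,
        f_percent=float(f_percent),
        va_cm_s=va,
        va_source=source,
        foi=va * VA_WEIGHT + f_percent * F_WEIGHT,
    )


def foi_table(
    roi_f: Iterable[ROIFStats],
    measured_va: Mapping[str, float] | None = None,
    mapping: Mapping[str, str] | None = None,
    curve: VAFCurve = DEFAULT_CURVE,
) -> list[FOIRecord]:
    """Assemble the per-region FOI table over all 45 IVIM ROIs.

    ``measured_va`` maps flow-ROI names to measured VA (cm/s); each is
    attached to its IVIM region through ``mapping`` (default: the packaged
    flow-to-IVIM vocabulary, in which the lower cerebral aqueduct on 4D flow
    feeds the upper fourth ventricle on IVIM).  Regions without a measured
    VA get the curve estimate.  The region mean ``f`` drives both formulas.
    """
    vocab = roi_vocabulary()
    if mapping is None:
        mapping = vocab["flow_to_ivim"]
    measured_va = dict(measured_va or {})

    stats = list(roi_f)
    names = [s.roi_name for s in stats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ROI names in roi_f")
    missing = set(vocab["ivim_rois"]) - set(names)
    if missing:
        raise ValueError(f"missing f statistics for ROIs: {sorted(missing)}")

    va_by_ivim_roi: dict[str, float] = {}
    for flow_name, va in measured_va.items():
        if flow_name not in mapping:
            raise ValueError(f"unknown flow ROI '{flow_name}'")
        va_by_ivim_roi[mapping[flow_name]] = float(va)

    order = {name: i for i, name in enumerate(vocab["ivim_rois"])}
    records = []
    for s in sorted(stats, key=lambda s: order.get(s.roi_name, len(order))):
        records.append(
            compute_foi(
                s.mean_f,
                va_cm_s=va_by_ivim_roi.get(s.roi_name),
                roi_name=s.roi_name,
                curve=curve,
            )
        )
    return records
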