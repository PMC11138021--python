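"""Cardiac-gated CSF flow quantification from 4D-flow MRI waveforms.

CSF moves bidirectionally with the cardiac cycle, so every metric here is
defined on a signed through-plane velocity waveform sampled at the cardiac
phases of one heartbeat:

* velocity amplitude (VA): max - min of the signed velocity series, cm/s —
  the peak-to-peak excursion of the oscillation;
* stroke volume: half the total oscillatory volume (forward + backward)/2
  per heartbeat, in microlitres;
* net flow volume: forward minus backward volume per heartbeat;
* reverse flow rate: the percentage of the total moved volume that went in
  the minority direction (50% for a pure zero-mean oscillation).

Flow rate uses the unit identity 1 cm/s x 1 mm^2 = 10 uL/s, applied once in
:func:`flow_metrics`.  Integration is periodic trapezoid (the cycle is
closed by repeating phase 0 at the end of the period).

:func:`correct_phase_offset` removes the slowly varying phase-offset /
eddy-current background of a phase-contrast velocity field by fitting a low
order 3D polynomial to static-tissue voxels and subtracting it everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VelocityWaveform",
    "FlowMetrics",
    "correct_phase_offset",
    "velocity_amplitude",
    "flow_metrics",
]


@dataclass(frozen=True)
class VelocityWaveform:
    """Per-ROI signed velocity series over one cardiac cycle.

    ``phase_times`` are fractions of the cycle in [0, 1), strictly
    increasing; ``mean_velocity`` is the spatial-mean through-plane velocity
    per phase and ``peak_velocity`` the signed spatial extremum per phase,
    both in cm/s.  ``area_mm2`` is the ROI cross-section.
    """

    roi_name: str
    phase_times: np.ndarray
    mean_velocity: np.ndarray
    peak_velocity: np.ndarray
    area_mm2: float
    heart_period_s: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.phase_times, dtype=float)
        vm = np.asarray(self.mean_velocity, dtype=float)
        vp = np.asarray(self.peak_velocity, dtype=float)
        if t.size < 4:
            raise ValueError("waveform needs at least 4 cardiac phases")
        if not (t.size == vm.size == vp.size):
            raise ValueError("phase_times and velocity series must have equal length")
        if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= 1:
            raise ValueError("phase_times must be strictly increasing within [0, 1)")
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        if self.heart_period_s <= 0:
            raise ValueError("heart_period_s must be positive")
        object.__setattr__(self, "phase_times", t)
        object.__setattr__(self, "mean_velocity", vm)
        object.__setattr__(self, "peak_velocity", vp)


@dataclass(frozen=True)
class FlowMetrics:
    """Derived per-ROI flow metrics for one cardiac cycle."""

    va_cm_s: float
    abs_max_velocity_cm_s: float
    mean_velocity_cm_s: float
    stroke_volume_uL: float
    net_flow_uL: float
    reverse_flow_pct: float


def correct_phase_offset(
    velocity_volume: np.ndarray,
    static_mask: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Subtract a polynomial background fitted to static-tissue voxels.

    A least-squares polynomial of total degree ``order`` (0-3) in the voxel
    coordinates is fitted to the velocities inside ``static_mask`` and
    subtracted from the whole field, removing phase offsets and
    eddy-current-induced background so slow CSF velocities are measured
    against a true zero.
    """
    field = np.asarray(velocity_volume, dtype=float)
    mask = np.asarray(static_mask, dtype=bool)
    if field.ndim != 3 or mask.shape != field.shape:
        raise ValueError("velocity_volume must be 3D with a matching static_mask")
    if order not in (0, 1, 2, 3):
        raise ValueError("polynomial order must be 0, 1, 2 or 3")
    if not mask.any():
        raise ValueError("static_mask is empty")

    exponents = [
        (i, j, k)
        for i, j, k in itertools.product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]
    if mask.sum() < len(exponents):
        raise ValueError(
            f"{int(mask.sum())} static voxels cannot constrain "
            f"{len(exponents)} polynomial coefficients"
        )
    # Normalized coordinates keep the Vandermonde matrix well conditioned.
    grids = np.meshgrid(*[np.linspace(0.0, 1.0, n) for n in field.shape], indexing="ij")

    def design(sel: np.ndarray | slice) -> np.ndarray:
        cols = [
            grids[0][sel] ** i * grids[1][sel] ** j * grids[2][sel] ** k
            for i, j, k in exponents
        ]
        return np.stack([c.ravel() for c in cols], axis=1)

    coeffs, *_ = np.linalg.lstsq(design(mask), field[mask].ravel(), rcond=None)
    background = (design(slice(None)) @ coeffs).reshape(field.shape)
    return field - background


def velocity_amplitude(waveform: VelocityWaveform, channel: str = "peak") -> float:
    """Peak-to-peak velocity excursion, max(v) - min(v), in cm/s.

    ``channel`` selects the per-phase spatial extremum series (``"peak"``,
    default) or the spatial-mean series (``"mean"``).
    """
    series = _channel(waveform, channel)
    return float(series.max() - series.min())


def _channel(waveform: VelocityWaveform, channel: str) -> np.ndarray:
    if channel == "peak":
        return waveform.peak_velocity
    if channel == "mean":
        return waveform.mean_velocity
    raise ValueError(f"unknown velocity channel '{channel}'")


def flow_metrics(waveform: VelocityWaveform, va_channel: str = "peak") -> FlowMetrics:
    """Compute all per-ROI flow metrics from one cardiac-cycle waveform.

    The instantaneous volumetric rate is Q_k = mean_velocity_k * area * 10
    in uL/s.  Forward volume F integrates max(Q, 0) and backward volume B
    integrates max(-Q, 0) over one closed cycle (periodic trapezoid);
    stroke = (F + B) / 2, net = F - B and reverse = 100 * min(F, B)/(F + B)
    (0 when nothing moves).
    """
    t = np.append(waveform.phase_times, waveform.phase_times[0] + 1.0)
    t_s = t * waveform.heart_period_s
    v = np.append(waveform.mean_velocity, waveform.mean_velocity[0])
    q = v * waveform.area_mm2 * 10.0  # uL/s

    forward = float(np.trapezoid(np.maximum(q, 0.0), t_s))
    backward = float(np.trapezoid(np.maximum(-q, 0.0), t_s))
    total = forward + backward
    reverse_pct = 100.0 * min(forward, backward) / total if total > 0 else 0.0

    peak = waveform.peak_velocity
    return FlowMetrics(
        va_cm_s=velocity_amplitude(waveform, va_channel),
        abs_max_velocity_cm_s=float(np.abs(peak).max()),
        mean_velocity_cm_s=float(np.trapezoid(v, t) / (t[-1] - t[0])),
        stroke_volume_uL=(forward + backward) / 2.0,
        net_flow_uL=forward - backward,
        reverse_flow_pct=reverse_pct,
    )
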