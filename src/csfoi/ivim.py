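"""Biexponential intravoxel incoherent motion (IVIM) model fitting.

The IVIM model decomposes the diffusion-weighted MRI signal of a voxel into a
fast pseudo-diffusion pool (perfusion fraction ``f``, pseudo-diffusion
coefficient ``D*``) and a slow true-diffusion pool (coefficient ``D``):

    S(b) / S(0) = f * exp(-b * D*) + (1 - f) * exp(-b * D)

For CSF-space voxels the pseudo-diffusion pool reflects incoherent pulsatile
fluid motion rather than capillary perfusion, so ``f`` serves as a proxy for
fluid oscillation.  This module provides the forward model, a monoexponential
ADC fit, constrained voxelwise least-squares IVIM fitting with segmented
initialization, volume-level map production, and per-ROI ``f`` statistics.

Units: b-values in s/mm^2, diffusivities in mm^2/s.  ``f`` is a fraction
internally; parameter maps and ROI statistics report it in percent (the
single fraction-to-percent conversion happens at the map boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DWIStack",
    "IVIMParams",
    "ParameterMaps",
    "ROIFStats",
    "FitOptions",
    "FitFlag",
    "biexp_signal",
    "fit_adc",
    "fit_ivim_voxel",
    "fit_ivim_volume",
    "roi_f_stats",
]

# Box constraints for the constrained least-squares fit (mm^2/s for rates).
F_MIN, F_MAX = 1e-4, 1.0 - 1e-4
D_MIN, D_MAX = 1e-5, 1e-2
DSTAR_MAX = 1.0
# Below this fitted f the biexponential degenerates to a monoexponential and
# D* carries essentially no information.
F_RELIABLE_MIN = 0.01


class FitFlag(IntEnum):
    """Per-voxel fit status stored in :class:`ParameterMaps`."""

    OK = 0
    FAILED = 1
    MASKED_OUT = 2


@dataclass(frozen=True)
class DWIStack:
    """A 4D multi-b-value diffusion-weighted volume.

    Parameters
    ----------
    signal
        Nonnegative array of shape ``(x, y, z, n_b)``; arbitrary units.
    b_values
        Diffusion weightings in s/mm^2, one per 4th-dimension index; must
        include 0 (the unweighted reference S0).
    mask
        Boolean volume selecting voxels to fit.
    voxel_size
        Voxel edge lengths in mm.
    """

    signal: np.ndarray
    b_values: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        b_values = np.asarray(self.b_values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if signal.ndim != 4:
            raise ValueError(f"signal must be 4D (x, y, z, b), got ndim={signal.ndim}")
        if signal.shape[3] != b_values.size:
            raise ValueError(
                f"4th dimension length {signal.shape[3]} does not match "
                f"{b_values.size} b-values"
            )
        if 0.0 not in b_values:
            raise ValueError("b_values must include 0 (the S0 reference)")
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal contains non-finite values")
        if mask.shape != signal.shape[:3]:
            raise ValueError("mask shape must match the spatial signal shape")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "b_values", b_values)
        object.__setattr__(self, "mask", mask)

    @property
    def b0_index(self) -> int:
        return int(np.flatnonzero(self.b_values == 0.0)[0])


@dataclass(frozen=True)
class IVIMParams:
    """Voxel-level IVIM estimates with fit diagnostics.

    ``dstar_reliable`` is False when the fitted perfusion fraction is so small
    (< 1%) that the fast compartment is unidentifiable and ``D_star`` should
    not be interpreted.
    """

    f: float
    D: float
    D_star: float
    adc: float
    rss: float
    converged: bool
    n_iter: int
    dstar_reliable: bool = True


@dataclass
class ParameterMaps:
    """Volume-level IVIM parameter maps; ``f_percent`` is in percent [0, 100]."""

    f_percent: np.ndarray
    D: np.ndarray
    D_star: np.ndarray
    adc: np.ndarray
    mask: np.ndarray
    fit_flags: np.ndarray
    provenance: str = ""


@dataclass(frozen=True)
class ROIFStats:
    """Mean/max/min perfusion fraction (percent) over one ROI."""

    roi_name: str
    mean_f: float
    max_f: float
    min_f: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (self.min_f <= self.mean_f <= self.max_f):
            raise ValueError("ROI statistics must satisfy min <= mean <= max")
        if self.n_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")


@dataclass(frozen=True)
class FitOptions:
    """Options for the constrained voxelwise fit.

    ``segmented_b_min`` is the smallest b-value used in the log-linear
    initialization of D (high-b regime where the fast pool has decayed).

    ``noise_sigma`` optionally enables the standard magnitude-MRI noise-floor
    correction: when the per-channel noise level sigma is known, each signal
    sample is replaced by sqrt(max(M^2 - 2*sigma^2, 0)) before fitting.
    Magnitude (Rician) noise adds a positive floor that flattens the high-b
    tail and biases f upward and D downward in a plain least-squares fit;
    the correction removes the floor in expectation.
    """

    segmented_b_min: float = 250.0
    noise_sigma: float | None = None
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 400


def biexp_signal(
    f: float | np.ndarray,
    D: float | np.ndarray,
    D_star: float | np.ndarray,
    b: float | np.ndarray,
) -> float | np.ndarray:
    """Relative IVIM signal S/S0 = f*exp(-b*D*) + (1-f)*exp(-b*D).

    All inputs must be nonnegative and ``f`` at most 1.  Broadcasts over
    array inputs.
    """
    f = np.asarray(f, dtype=float)
    D = np.asarray(D, dtype=float)
    D_star = np.asarray(D_star, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f must lie in [0, 1]")
    if np.any(D < 0) or np.any(D_star < 0) or np.any(b < 0):
        raise ValueError("D, D_star and b must be nonnegative")
    out = f * np.exp(-b * D_star) + (1.0 - f) * np.exp(-b * D)
    return float(out) if out.ndim == 0 else out


def fit_adc(signal: Sequence[float], b_values: Sequence[float]) -> float:
    """Apparent diffusion coefficient from a log-linear fit across all b.

    Fits ordinary least squares to ``(b, -ln(S/S0))`` over every b with
    positive signal and returns the slope in mm^2/s.  S0 is the signal at
    b = 0; an intercept is estimated so noise at b=0 does not bias the slope.
    """
    signal = np.asarray(signal, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if signal.shape != b_values.shape:
        raise ValueError("signal and b_values must have identical length")
    b0_idx = np.flatnonzero(b_values == 0.0)
    if b0_idx.size == 0 or signal[b0_idx[0]] <= 0:
        raise ValueError("ADC fit requires a positive S0 at b = 0")
    s0 = signal[b0_idx[0]]
    keep = signal > 0
    if np.unique(b_values[keep]).size < 2:
        raise ValueError("ADC fit requires positive signal at >= 2 distinct b-values")
    y = -np.log(signal[keep] / s0)
    slope, _ = np.polyfit(b_values[keep], y, 1)
    return float(slope)


def _segmented_init(norm_signal: np.ndarray, b_values: np.ndarray,
                    options: FitOptions) -> np.ndarray:
    """Two-step initialization: D from the high-b log-linear tail, then
    f0 = 1 - exp(intercept) and D*0 = 10 * D0."""
    high = (b_values >= options.segmented_b_min) & (norm_signal > 0)
    if high.sum() >= 2 and np.unique(b_values[high]).size >= 2:
        slope, intercept = np.polyfit(b_values[high], np.log(norm_signal[high]), 1)
        d0 = float(np.clip(-slope, D_MIN, D_MAX))
        f0 = float(np.clip(1.0 - np.exp(intercept), 0.01, 0.99))
    else:
        d0, f0 = 1e-3, 0.1
    dstar0 = min(10.0 * d0, DSTAR_MAX)
    return np.array([f0, d0, dstar0 - d0])


def fit_ivim_voxel(
    signal: Sequence[float],
    b_values: Sequence[float],
    options: FitOptions | None = None,
) -> IVIMParams:
    """Constrained biexponential least-squares fit for one voxel.

    Minimizes sum_b (S_b/S0 - model)^2 with box constraints f in (0, 1),
    D in [1e-5, 1e-2] mm^2/s and D* in [D, 1] mm^2/s, using a bounded
    trust-region least-squares solver seeded by segmented initialization.
    The D* >= D ordering is enforced by fitting delta = D* - D >= 0.
    Non-convergence returns the best iterate with ``converged=False`` rather
    than raising.
    """
    options = options or FitOptions()
    signal = np.asarray(signal, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if signal.size != b_values.size or signal.size < 4:
        raise ValueError("need matching signal/b vectors of length >= 4")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if options.noise_sigma is not None:
        floor = 2.0 * options.noise_sigma**2
        signal = np.sqrt(np.maximum(signal**2 - floor, 0.0))
    b0_idx = np.flatnonzero(b_values == 0.0)
    if b0_idx.size == 0 or signal[b0_idx[0]] <= 0:
        raise ValueError("IVIM fit requires a positive S0 at b = 0")
    s0 = signal[b0_idx[0]]
    y = signal / s0

    def residuals(x: np.ndarray) -> np.ndarray:
        f, d, delta = x
        return f * np.exp(-b_values * (d + delta)) + (1.0 - f) * np.exp(-b_values * d) - y

    x0 = _segmented_init(y, b_values, options)
    lower = np.array([F_MIN, D_MIN, 0.0])
    upper = np.array([F_MAX, D_MAX, DSTAR_MAX])
    x0 = np.clip(x0, lower, upper)
    result = least_squares(
        residuals, x0, bounds=(lower, upper), method="trf",
        xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
        max_nfev=options.max_nfev,
    )
    f_hat, d_hat, delta_hat = result.x
    dstar_hat = d_hat + delta_hat
    try:
        adc = fit_adc(signal, b_values)
    except ValueError:
        adc = float("nan")
    return IVIMParams(
        f=float(f_hat),
        D=float(d_hat),
        D_star=float(dstar_hat),
        adc=adc,
        rss=float(2.0 * result.cost),
        converged=bool(result.status > 0),
        n_iter=int(result.nfev),
        dstar_reliable=bool(f_hat >= F_RELIABLE_MIN),
    )


def fit_ivim_volume(stack: DWIStack, options: FitOptions | None = None) -> ParameterMaps:
    """Voxelwise IVIM fit over every masked voxel of a :class:`DWIStack`.

    Returns parameter maps with ``f`` in percent.  Voxels outside the mask
    carry NaN and ``fit_flags=MASKED_OUT``; voxels whose fit raises (e.g.
    nonpositive S0) carry NaN and ``fit_flags=FAILED``.  Voxel fits are
    independent, so the result does not depend on traversal order.
    """
    options = options or FitOptions()
    if not stack.mask.any():
        raise ValueError("mask is empty: no voxels to fit")
    shape = stack.signal.shape[:3]
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(
        f_percent=nan.copy(), D=nan.copy(), D_star=nan.copy(), adc=nan.copy(),
        mask=stack.mask.copy(),
        fit_flags=np.full(shape, FitFlag.MASKED_OUT, dtype=np.int8),
    )
    for idx in np.argwhere(stack.mask):
        i, j, k = idx
        try:
            p = fit_ivim_voxel(stack.signal[i, j, k, :], stack.b_values, options)
        except ValueError:
            maps.fit_flags[i, j, k] = FitFlag.FAILED
            continue
        maps.f_percent[i, j, k] = 100.0 * p.f
        maps.D[i, j, k] = p.D
        maps.D_star[i, j, k] = p.D_star
        maps.adc[i, j, k] = p.adc
        maps.fit_flags[i, j, k] = FitFlag.OK
    return maps


def roi_f_stats(maps: ParameterMaps, labels: np.ndarray, roi_name: str,
                label_value: int) -> ROIFStats:
    """Mean, maximum and minimum ``f`` (percent) over one labeled ROI.

    Only voxels with a successful fit contribute; an ROI with no usable
    voxels raises a ValueError naming the ROI.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.f_percent.shape:
        raise ValueError("label volume shape must match the parameter maps")
    voxels = (labels == label_value) & (maps.fit_flags == FitFlag.OK)
    if not voxels.any():
        raise ValueError(f"ROI '{roi_name}' has no successfully fitted voxels")
    values = maps.f_percent[voxels]
    return ROIFStats(
        roi_name=roi_name,
        mean_f=float(values.mean()),
        max_f=float(values.max()),
        min_f=float(values.min()),
        n_voxels=int(values.size),
    )
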