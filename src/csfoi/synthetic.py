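"""Synthetic MRI inputs with the statistical structure the analysis assumes.

No imaging data accompany the study this package operationalizes, so every
downstream stage is exercised on simulated inputs that emulate the three
acquisition products:

* multi-b-value diffusion-weighted stacks following the biexponential IVIM
  forward model, with optional Gaussian or Rician (magnitude-MRI) noise,
  laid out as axis-aligned region blocks so ROI statistics are trivially
  verifiable;
* cardiac-gated per-ROI CSF velocity waveforms — near-zero-mean sinusoidal
  oscillations sampled at 8 or 12 uniform cardiac phases, clipped at the
  velocity-encoding limit (venc, 5 cm/s), with analytic ground-truth flow
  metrics;
* two-group cohort tables (three healthy age bands plus a Hakim-like
  group) whose morphometric, f and VA distributions mimic the published
  cohort summaries, with optional within-group correlations via a Gaussian
  copula factor.

All generators are seeded and bit-reproducible: identical config + seed
gives identical arrays/tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .flow import FlowMetrics, VelocityWaveform
from .ivim import DWIStack, FitFlag, ParameterMaps, biexp_signal

__all__ = [
    "RegionParams",
    "SyntheticDWIConfig",
    "SyntheticFlowConfig",
    "SyntheticCohortConfig",
    "SimulatedDWI",
    "SimulatedFlow",
    "simulate_dwi",
    "simulate_velocity_waveforms",
    "simulate_cohort",
    "default_flow_config",
    "default_cohort_config",
    "TABLE_FLOW_ROI_STATS",
    "COHORT_MEASUREMENTS",
]

DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0)

#: Ratio of the spatial-peak to the spatial-mean velocity oscillation used
#: for the synthetic peak channel (plug-profile flow would give 1; parabolic
#: laminar flow 2; 1.5 is an intermediate, blunted profile).
PEAK_FACTOR = 1.5

#: Published per-ROI cohort summaries used as simulation targets:
#: (VA mean, VA SD) cm/s and (f mean, f SD) percent at the 7 flow regions.
TABLE_FLOW_ROI_STATS: dict[str, dict[str, float]] = {
    "foramen_magnum_dorsal": {"va": 1.33, "va_sd": 0.61, "f": 70.2, "f_sd": 16.6},
    "prepontine_cistern": {"va": 1.27, "va_sd": 0.72, "f": 87.3, "f_sd": 4.5},
    "foramen_of_magendie": {"va": 0.49, "va_sd": 0.32, "f": 76.4, "f_sd": 8.4},
    "lower_cerebral_aqueduct": {"va": 0.78, "va_sd": 0.50, "f": 75.6, "f_sd": 7.5},
    "upper_cerebral_aqueduct": {"va": 0.94, "va_sd": 0.70, "f": 71.2, "f_sd": 11.1},
    "lt_foramen_of_monro": {"va": 0.48, "va_sd": 0.26, "f": 74.7, "f_sd": 12.9},
    "rt_foramen_of_monro": {"va": 0.41, "va_sd": 0.26, "f": 72.8, "f_sd": 14.2},
}

#: Approximate ROI cross-sections, mm^2 (order-of-magnitude anatomy).
_DEFAULT_AREAS: dict[str, float] = {
    "foramen_magnum_dorsal": 150.0,
    "prepontine_cistern": 60.0,
    "foramen_of_magendie": 12.0,
    "lower_cerebral_aqueduct": 4.0,
    "upper_cerebral_aqueduct": 4.0,
    "lt_foramen_of_monro": 6.0,
    "rt_foramen_of_monro": 6.0,
}

#: Published cohort summary (mean, SD) per measurement and group: the three
#: healthy age bands and the Hakim group.
COHORT_MEASUREMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "evans_index": {
        "under40": (0.25, 0.02), "40to59": (0.25, 0.02),
        "over60": (0.26, 0.02), "hakim": (0.37, 0.18),
    },
    "z_evans_index": {
        "under40": (0.24, 0.03), "40to59": (0.24, 0.03),
        "over60": (0.27, 0.04), "hakim": (0.43, 0.14),
    },
    "bvr_ac": {
        "under40": (2.1, 0.3), "40to59": (2.1, 0.3),
        "over60": (1.8, 0.4), "hakim": (0.83, 0.27),
    },
    "bvr_pc": {
        "under40": (4.8, 1.4), "40to59": (4.3, 1.1),
        "over60": (3.0, 1.0), "hakim": (0.99, 0.22),
    },
    "callosal_angle": {
        "under40": (119.9, 9.4), "40to59": (118.7, 11.4),
        "over60": (117.0, 11.5), "hakim": (68.9, 16.7),
    },
    "ventricle_volume_ml": {
        "under40": (19.5, 7.5), "40to59": (22.0, 8.2),
        "over60": (36.4, 14.3), "hakim": (127.0, 33.5),
    },
    "ventricle_pct": {
        "under40": (1.3, 0.5), "40to59": (1.5, 0.5),
        "over60": (2.5, 0.9), "hakim": (8.4, 1.8),
    },
}

#: Published healthy/patient counts per group.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "under40": 45, "40to59": 46, "over60": 36, "hakim": 44,
}

#: Published female:male counts per group.
DEFAULT_SEX_COUNTS: dict[str, tuple[int, int]] = {
    "under40": (30, 15), "40to59": (32, 14), "over60": (21, 15), "hakim": (28, 16),
}


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth IVIM parameters for one region block of the phantom."""

    label: str
    f: float
    D: float
    D_star: float
    S0: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise ValueError(f"region '{self.label}': f must lie in (0, 1)")
        if not 0 < self.D < self.D_star:
            raise ValueError(f"region '{self.label}': need 0 < D < D*")
        if self.S0 <= 0:
            raise ValueError(f"region '{self.label}': S0 must be positive")


@dataclass(frozen=True)
class SyntheticDWIConfig:
    """Configuration of the block phantom DWI simulation.

    ``snr`` is S0 over the complex-channel noise sigma (the largest region
    S0 when regions differ).  b-values default to the six-point CSF scheme
    0, 50, 100, 250, 500, 1000 s/mm^2.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    region_params: tuple[RegionParams, ...] = (
        RegionParams("csf_like", f=0.75, D=3e-3, D_star=3e-2, S0=1000.0),
        RegionParams("tissue_like", f=0.15, D=8e-4, D_star=1e-2, S0=800.0),
    )
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    noise_model: str = "rician"  # none | gaussian | rician
    snr: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if b[0] != 0.0:
            raise ValueError("b_values must start at 0")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise_model '{self.noise_model}'")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not self.region_params:
            raise ValueError("need at least one region")


class SimulatedDWI(NamedTuple):
    """Simulated stack plus its ground truth and region-label volume."""

    stack: DWIStack
    truth: ParameterMaps
    labels: np.ndarray
    label_values: dict[str, int]


def simulate_dwi(config: SyntheticDWIConfig) -> SimulatedDWI:
    """Simulate a multi-b-value DWI stack from the biexponential forward model.

    Regions are contiguous axis-aligned blocks along the first axis, labeled
    1..n_regions in ``labels``.  The noise-free voxel signal is
    S0 * (f e^{-b D*} + (1-f) e^{-b D}); Gaussian noise adds one real
    channel, Rician noise takes the magnitude of the complex-perturbed
    signal (always nonnegative, positively biased at low SNR).
    """
    nx, ny, nz = config.grid_shape
    n_regions = len(config.region_params)
    if nx < n_regions:
        raise ValueError("first grid axis shorter than the number of regions")
    b = np.asarray(config.b_values, dtype=float)

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    f_vol = np.zeros((nx, ny, nz))
    d_vol = np.zeros_like(f_vol)
    dstar_vol = np.zeros_like(f_vol)
    s0_vol = np.zeros_like(f_vol)
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    label_values = {}
    for value, (start, stop, params) in enumerate(
        zip(edges[:-1], edges[1:], config.region_params), start=1
    ):
        labels[start:stop] = value
        f_vol[start:stop] = params.f
        d_vol[start:stop] = params.D
        dstar_vol[start:stop] = params.D_star
        s0_vol[start:stop] = params.S0
        label_values[params.label] = value

    signal = s0_vol[..., None] * biexp_signal(
        f_vol[..., None], d_vol[..., None], dstar_vol[..., None], b[None, None, None, :]
    )
    if config.noise_model != "none":
        rng = np.random.default_rng(config.seed)
        sigma = max(p.S0 for p in config.region_params) / config.snr
        eps1 = rng.normal(0.0, sigma, signal.shape)
        if config.noise_model == "gaussian":
            signal = signal + eps1
        else:  # rician: magnitude of the complex-perturbed signal
            eps2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.hypot(signal + eps1, eps2)

    mask = np.ones((nx, ny, nz), dtype=bool)
    stack = DWIStack(signal=signal, b_values=b, mask=mask)
    truth = ParameterMaps(
        f_percent=100.0 * f_vol, D=d_vol, D_star=dstar_vol,
        adc=np.full_like(f_vol, np.nan), mask=mask,
        fit_flags=np.full((nx, ny, nz), FitFlag.OK, dtype=np.int8),
        provenance=f"synthetic seed={config.seed}",
    )
    return SimulatedDWI(stack=stack, truth=truth, labels=labels,
                        label_values=label_values)


@dataclass(frozen=True)
class SyntheticFlowConfig:
    """Configuration of the per-ROI cardiac velocity waveform simulation.

    ``amplitude_cm_s`` is the spatial-mean oscillation amplitude per ROI;
    the synthetic peak channel scales it by :data:`PEAK_FACTOR`.  Velocities
    are clipped at +/- ``venc_cm_s`` after noise, emulating the encoding
    ceiling of phase-contrast MRI.
    """

    roi_names: tuple[str, ...]
    amplitude_cm_s: Mapping[str, float]
    net_offset_cm_s: Mapping[str, float]
    area_mm2: Mapping[str, float]
    n_phases: int = 12
    heart_period_s: float = 1.0
    noise_sd_cm_s: float = 0.0
    venc_cm_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 4:
            raise ValueError("n_phases must be >= 4 (extrema unsampleable below)")
        if self.venc_cm_s <= 0 or self.heart_period_s <= 0:
            raise ValueError("venc_cm_s and heart_period_s must be positive")
        if self.noise_sd_cm_s < 0:
            raise ValueError("noise_sd_cm_s must be nonnegative")
        for roi in self.roi_names:
            for mapping, what in (
                (self.amplitude_cm_s, "amplitude_cm_s"),
                (self.net_offset_cm_s, "net_offset_cm_s"),
                (self.area_mm2, "area_mm2"),
            ):
                if roi not in mapping:
                    raise ValueError(f"missing {what} for ROI '{roi}'")
            if self.amplitude_cm_s[roi] < 0:
                raise ValueError("amplitudes must be nonnegative")
            if self.area_mm2[roi] <= 0:
                raise ValueError("areas must be positive")


class SimulatedFlow(NamedTuple):
    """Simulated waveforms plus analytic ground-truth metrics per ROI."""

    waveforms: list[VelocityWaveform]
    truth: dict[str, FlowMetrics]


def default_flow_config(
    n_phases: int = 12, noise_sd_cm_s: float = 0.02, seed: int = 0
) -> SyntheticFlowConfig:
    """Seven-ROI flow configuration whose peak-channel velocity amplitudes
    match the published per-ROI VA means."""
    rois = tuple(TABLE_FLOW_ROI_STATS)
    return SyntheticFlowConfig(
        roi_names=rois,
        # peak-channel VA = 2 * PEAK_FACTOR * A, so A = VA / (2 * PEAK_FACTOR)
        amplitude_cm_s={
            r: TABLE_FLOW_ROI_STATS[r]["va"] / (2.0 * PEAK_FACTOR) for r in rois
        },
        net_offset_cm_s={r: 0.01 for r in rois},
        area_mm2=dict(_DEFAULT_AREAS),
        n_phases=n_phases,
        noise_sd_cm_s=noise_sd_cm_s,
        seed=seed,
    )


def _analytic_oscillation_metrics(
    amplitude: float, offset: float, area_mm2: float, period_s: float
) -> FlowMetrics:
    """Closed-form flow metrics of v(t) = offset + amplitude*sin(2*pi*t/T).

    With Q = 10*area*v uL/s, C = 10*area*offset and A = 10*area*amplitude,
    the forward volume over one period is
    F = (T/2pi) * [C*(pi + 2*asin(r)) + 2*A*sqrt(1-r^2)],  r = C/A,
    and B = F - C*T (one-sided flow when |C| >= A).
    """
    c = 10.0 * area_mm2 * offset
    a = 10.0 * area_mm2 * amplitude
    net = c * period_s
    if a == 0.0 or abs(c) >= a:
        forward = max(net, 0.0)
        backward = max(-net, 0.0)
    else:
        r = c / a
        forward = (period_s / (2.0 * math.pi)) * (
            c * (math.pi + 2.0 * math.asin(r)) + 2.0 * a * math.sqrt(1.0 - r * r)
        )
        backward = forward - net
    total = forward + backward
    peak_amp = PEAK_FACTOR * amplitude
    return FlowMetrics(
        va_cm_s=2.0 * peak_amp,
        abs_max_velocity_cm_s=max(abs(offset + peak_amp), abs(offset - peak_amp)),
        mean_velocity_cm_s=offset,
        stroke_volume_uL=total / 2.0,
        net_flow_uL=net,
        reverse_flow_pct=100.0 * min(forward, backward) / total if total > 0 else 0.0,
    )


def simulate_velocity_waveforms(config: SyntheticFlowConfig) -> SimulatedFlow:
    """Simulate sinusoidal cardiac velocity waveforms for each flow ROI.

    Per ROI, the spatial-mean series is v_k = offset + A*sin(2*pi*k/n) plus
    optional Gaussian noise, sampled at the left endpoints k/n of one cycle
    (retrospective gating convention; for n divisible by 4 the sine extrema
    are sampled exactly).  Ground-truth metrics come from the closed-form
    integrals of the noise-free, unclipped waveform.
    """
    rng = np.random.default_rng(config.seed)
    k = np.arange(config.n_phases)
    phase_times = k / config.n_phases
    carrier = np.sin(2.0 * np.pi * phase_times)

    waveforms, truth = [], {}
    for roi in config.roi_names:
        amp = config.amplitude_cm_s[roi]
        offset = config.net_offset_cm_s[roi]
        mean_v = offset + amp * carrier
        peak_v = offset + PEAK_FACTOR * amp * carrier
        if config.noise_sd_cm_s > 0:
            mean_v = mean_v + rng.normal(0.0, config.noise_sd_cm_s, mean_v.shape)
            peak_v = peak_v + rng.normal(0.0, config.noise_sd_cm_s, peak_v.shape)
        mean_v = np.clip(mean_v, -config.venc_cm_s, config.venc_cm_s)
        peak_v = np.clip(peak_v, -config.venc_cm_s, config.venc_cm_s)
        waveforms.append(
            VelocityWaveform(
                roi_name=roi,
                phase_times=phase_times,
                mean_velocity=mean_v,
                peak_velocity=peak_v,
                area_mm2=config.area_mm2[roi],
                heart_period_s=config.heart_period_s,
            )
        )
        truth[roi] = _analytic_oscillation_metrics(
            amp, offset, config.area_mm2[roi], config.heart_period_s
        )
    return SimulatedFlow(waveforms=waveforms, truth=truth)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of the two-group (healthy bands + Hakim) cohort draw.

    ``measurements`` maps measurement name -> group -> (mean, SD).
    ``correlations`` optionally maps measurement-name pairs to a Pearson
    correlation imposed within every group (Gaussian copula factorization).
    ``sex_counts`` maps group -> (n_female, n_male).
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    measurements: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COHORT_MEASUREMENTS.items()}
    )
    correlations: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sex_counts: Mapping[str, tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group counts must be positive")
        names = list(self.measurements)
        for m, per_group in self.measurements.items():
            for g in self.group_sizes:
                if g not in per_group:
                    raise ValueError(f"measurement '{m}' lacks parameters for '{g}'")
                if per_group[g][1] < 0:
                    raise ValueError(f"measurement '{m}': SD must be >= 0")
        for (m1, m2), rho in self.correlations.items():
            if m1 not in names or m2 not in names:
                raise ValueError(f"correlation names unknown measurement ({m1}, {m2})")
            if not -1 < rho < 1:
                raise ValueError("correlations must lie in (-1, 1)")


def default_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Cohort configuration mimicking the published group summaries."""
    return SyntheticCohortConfig(
        sex_counts=dict(DEFAULT_SEX_COUNTS), seed=seed, **overrides
    )


def simulate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw a long cohort table: one row per subject x measurement.

    Values are Gaussian per group with the configured (mean, SD); the
    configured cross-measurement correlations are imposed through a
    Cholesky factor of the correlation matrix, so SD = 0 yields the mean
    exactly.  Columns: subject_id, group, sex, measurement, value.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.measurements)
    k = len(names)
    corr = np.eye(k)
    for (m1, m2), rho in config.correlations.items():
        i, j = names.index(m1), names.index(m2)
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc

    rows = []
    for group, n in config.group_sizes.items():
        z = rng.standard_normal((n, k)) @ chol.T
        means = np.array([config.measurements[m][group][0] for m in names])
        sds = np.array([config.measurements[m][group][1] for m in names])
        values = means + sds * z
        if config.sex_counts and group in config.sex_counts:
            n_f, n_m = config.sex_counts[group]
            sexes = (["F"] * n_f + ["M"] * n_m)[:n]
            sexes += ["F"] * (n - len(sexes))
        else:
            sexes = list(rng.choice(["F", "M"], size=n))
        for i in range(n):
            sid = f"{group}_{i:04d}"
            for j, m in enumerate(names):
                rows.append((sid, group, sexes[i], m, values[i, j]))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "sex", "measurement", "value"]
    )
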