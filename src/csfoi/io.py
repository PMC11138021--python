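"""File formats: NIfTI DWI stacks, FSL-style .bval text, and the CSV tables.

Conventions: comma-separated UTF-8 CSV with a header row and "." decimals;
every CSV written here opens with a single ``#`` comment line carrying the
tool version and a digest of the generating configuration, and is read back
with ``comment="#"``.  NIfTI volumes use the 4th dimension for the b-value
index; voxel indices are 0-based and world coordinates are ignored except
for the voxel size.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .flow import FlowMetrics, VelocityWaveform
from .foi import FOIRecord
from .ivim import DWIStack, ParameterMaps, ROIFStats

__all__ = [
    "config_digest",
    "read_dwi",
    "write_dwi",
    "write_parameter_maps",
    "read_labels",
    "write_labels",
    "write_csv",
    "read_csv",
    "write_waveforms",
    "read_waveforms",
    "write_flow_metrics",
    "read_flow_metrics",
    "write_roi_f_stats",
    "read_roi_f_stats",
    "write_foi_records",
]

_WAVEFORM_COLUMNS = [
    "roi", "phase_index", "phase_time_frac", "mean_velocity_cm_s",
    "peak_velocity_cm_s", "area_mm2", "heart_period_s",
]


def config_digest(config: object) -> str:
    """Short deterministic digest of a JSON-serializable configuration."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, config: object = None) -> None:
    """Write a CSV with the version/config-digest header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# csfoi {__version__} config={config_digest(config)}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_dwi(nifti_path: str | Path, bval_path: str | Path) -> DWIStack:
    """Load a 4D DWI NIfTI plus its whitespace-separated .bval file."""
    nifti_path, bval_path = Path(nifti_path), Path(bval_path)
    try:
        img = nib.load(str(nifti_path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI '{nifti_path}': {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"'{nifti_path}' is {data.ndim}D; a 4D (x,y,z,b) volume is required")
    try:
        b_values = np.loadtxt(bval_path, dtype=float).ravel()
    except Exception as exc:
        raise ValueError(f"cannot read b-values '{bval_path}': {exc}") from exc
    if b_values.size != data.shape[3]:
        raise ValueError(
            f"'{bval_path}' lists {b_values.size} b-values but '{nifti_path}' "
            f"holds {data.shape[3]} volumes"
        )
    zooms = img.header.get_zooms()[:3]
    mask = np.ones(data.shape[:3], dtype=bool)
    return DWIStack(signal=data, b_values=b_values, mask=mask,
                    voxel_size=tuple(float(z) for z in zooms))


def _nifti(data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> nib.Nifti1Image:
    affine = np.diag([*voxel_size, 1.0])
    return nib.Nifti1Image(np.asarray(data), affine)


def write_dwi(stack: DWIStack, nifti_path: str | Path, bval_path: str | Path) -> None:
    nib.save(_nifti(stack.signal, stack.voxel_size), str(nifti_path))
    with open(bval_path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(f"{b:g}" for b in stack.b_values) + "\n")


def write_parameter_maps(maps: ParameterMaps, out_dir: str | Path,
                         voxel_size=(1.0, 1.0, 1.0)) -> dict[str, Path]:
    """Write f (%), D, D*, ADC and fit-flag volumes as NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes = {
        "f_percent": maps.f_percent, "D": maps.D, "D_star": maps.D_star,
        "adc": maps.adc, "fit_flags": maps.fit_flags.astype(np.int16),
    }
    paths = {}
    for name, data in volumes.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(_nifti(data, voxel_size), str(p))
        paths[name] = p
    return paths


def write_labels(labels: np.ndarray, label_values: Mapping[str, int],
                 nifti_path: str | Path, sidecar_path: str | Path) -> None:
    """Integer ROI label volume plus a JSON name<->label sidecar."""
    nib.save(_nifti(labels.astype(np.int16)), str(nifti_path))
    Path(sidecar_path).write_text(
        json.dumps(dict(label_values), indent=2, sort_keys=True), encoding="utf-8"
    )


def read_labels(nifti_path: str | Path, sidecar_path: str | Path
                ) -> tuple[np.ndarray, dict[str, int]]:
    labels = np.asarray(nib.load(str(nifti_path)).dataobj).astype(np.int32)
    label_values = json.loads(Path(sidecar_path).read_text(encoding="utf-8"))
    return labels, {str(k): int(v) for k, v in label_values.items()}


def write_waveforms(waveforms: Iterable[VelocityWaveform], path: str | Path,
                    config: object = None) -> None:
    rows = []
    for w in waveforms:
        for i, t in enumerate(w.phase_times):
            rows.append((w.roi_name, i, t, w.mean_velocity[i], w.peak_velocity[i],
                         w.area_mm2, w.heart_period_s))
    write_csv(pd.DataFrame(rows, columns=_WAVEFORM_COLUMNS), path, config)


def read_waveforms(path: str | Path) -> list[VelocityWaveform]:
    df = read_csv(path)
    missing = set(_WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV '{path}' lacks columns: {sorted(missing)}")
    out = []
    for roi, sub in df.groupby("roi", sort=False):
        sub = sub.sort_values("phase_index")
        out.append(
            VelocityWaveform(
                roi_name=str(roi),
                phase_times=sub["phase_time_frac"].to_numpy(),
                mean_velocity=sub["mean_velocity_cm_s"].to_numpy(),
                peak_velocity=sub["peak_velocity_cm_s"].to_numpy(),
                area_mm2=float(sub["area_mm2"].iloc[0]),
                heart_period_s=float(sub["heart_period_s"].iloc[0]),
            )
        )
    return out


def write_flow_metrics(metrics: Mapping[str, FlowMetrics], path: str | Path,
                       config: object = None) -> None:
    rows = [
        (roi, m.va_cm_s, m.abs_max_velocity_cm_s, m.mean_velocity_cm_s,
         m.stroke_volume_uL, m.net_flow_uL, m.reverse_flow_pct)
        for roi, m in metrics.items()
    ]
    df = pd.DataFrame(rows, columns=[
        "roi", "va_cm_s", "abs_max_velocity_cm_s", "mean_velocity_cm_s",
        "stroke_volume_uL", "net_flow_uL", "reverse_flow_pct",
    ])
    write_csv(df, path, config)


def read_flow_metrics(path: str | Path) -> dict[str, FlowMetrics]:
    df = read_csv(path)
    return {
        str(row.roi): FlowMetrics(
            va_cm_s=row.va_cm_s,
            abs_max_velocity_cm_s=row.abs_max_velocity_cm_s,
            mean_velocity_cm_s=row.mean_velocity_cm_s,
            stroke_volume_uL=row.stroke_volume_uL,
            net_flow_uL=row.net_flow_uL,
            reverse_flow_pct=row.reverse_flow_pct,
        )
        for row in df.itertuples()
    }


def write_roi_f_stats(stats: Iterable[ROIFStats], path: str | Path,
                      config: object = None) -> None:
    df = pd.DataFrame(
        [(s.roi_name, s.mean_f, s.max_f, s.min_f, s.n_voxels) for s in stats],
        columns=["roi", "mean_f", "max_f", "min_f", "n_voxels"],
    )
    write_csv(df, path, config)


def read_roi_f_stats(path: str | Path) -> list[ROIFStats]:
    df = read_csv(path)
    return [
        ROIFStats(roi_name=str(r.roi), mean_f=r.mean_f, max_f=r.max_f,
                  min_f=r.min_f, n_voxels=int(r.n_voxels))
        for r in df.itertuples()
    ]


def write_foi_records(records: Iterable[FOIRecord], path: str | Path,
                      config: object = None) -> None:
    """FOI table CSV; VA rounded to 2 decimals and FOI to 1 in the report
    (full precision stays in memory)."""
    df = pd.DataFrame(
        [
            (r.roi_name, r.f_percent, round(r.va_cm_s, 2), r.va_source,
             round(r.foi, 1))
            for r in records
        ],
        columns=["roi", "f_percent", "va_cm_s", "va_source", "foi"],
    )
    write_csv(df, path, config)
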