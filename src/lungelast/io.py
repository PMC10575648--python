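"""File-format plumbing: NIfTI volumes, CSV signals/tables, YAML specs.

Conventions (declared here once, used everywhere): voxel indices are
0-based; world coordinates are index * spacing + origin in mm; DVFs are
stored as 3-component NIfTI volumes in world mm with the pull-back
(target-to-source) convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (
    BreathingSignal,
    LobeElasticityParams,
    PhantomSpec,
    ScanSet,
    TumorSpec,
)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data: np.ndarray, spacing) -> None:
    """Write a volume (scalar 3D or 3D+vector) as NIfTI with mm spacing."""
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def save_signal(path, signal: BreathingSignal) -> None:
    pd.DataFrame(
        {"time_s": signal.time, "amplitude": signal.amplitude,
         "flow": signal.flow}
    ).to_csv(path, index=False)


def load_signal(path) -> BreathingSignal:
    df = pd.read_csv(path)
    return BreathingSignal(
        time=df["time_s"].to_numpy(),
        amplitude=df["amplitude"].to_numpy(),
        flow=df["flow"].to_numpy(),
    )


def save_scan_set(directory, scans: ScanSet) -> None:
    """Write a scan set: one DVF NIfTI per scan plus a (v, f) CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(scans.n_scans):
        save_volume(directory / f"dvf_{i:03d}.nii", scans.dvfs[i],
                    scans.spacing)
    pd.DataFrame(
        {"scan": np.arange(scans.n_scans), "amplitude": scans.v,
         "flow": scans.f,
         "is_reference": np.arange(scans.n_scans) == scans.reference_index}
    ).to_csv(directory / "breathing_states.csv", index=False)


def load_scan_set(directory) -> ScanSet:
    directory = Path(directory)
    df = pd.read_csv(directory / "breathing_states.csv")
    dvfs, spacing = [], None
    for i in df["scan"]:
        d, spacing = load_volume(directory / f"dvf_{int(i):03d}.nii")
        dvfs.append(d)
    ref = int(df.index[df["is_reference"]][0])
    return ScanSet(
        dvfs=np.stack(dvfs), v=df["amplitude"].to_numpy(),
        f=df["flow"].to_numpy(), spacing=spacing, reference_index=ref,
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["spacing"] = list(spec.spacing)
    d["lobar_elasticity_params"] = [
        dataclasses.asdict(p) for p in spec.lobar_elasticity_params
    ]
    if spec.tumor_spec is not None:
        d["tumor_spec"] = {"lobes": list(spec.tumor_spec.lobes),
                           "radius_mm": spec.tumor_spec.radius_mm}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["grid_shape"] = tuple(d["grid_shape"])
    d["spacing"] = tuple(d["spacing"])
    d["lobar_elasticity_params"] = tuple(
        LobeElasticityParams(**p) for p in d["lobar_elasticity_params"]
    )
    if d.get("tumor_spec"):
        ts = d["tumor_spec"]
        d["tumor_spec"] = TumorSpec(tuple(ts["lobes"]), ts["radius_mm"])
    return PhantomSpec(**d)


def save_spec(path, spec: PhantomSpec) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec)))


def load_spec(path) -> PhantomSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
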