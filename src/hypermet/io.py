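"""Readers and writers for the pipeline's file formats.

Dynamic per-channel images travel as 4D NIfTI-1 (one file per channel,
voxel sizes from the protocol); per-coil complex data and the phantom's
ground-truth sidecar use HDF5; covariance matrices and summary tables are
CSV; configs are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import BolusParams, PhantomGroundTruth
from .preprocess import CoilStack, DynamicSeries, NoiseCovariance
from .protocol import AcquisitionProtocol

__all__ = [
    "series_affine",
    "save_series_nifti",
    "load_series_nifti",
    "save_coil_stack",
    "load_coil_stack",
    "save_ground_truth",
    "load_ground_truth",
    "save_covariance_csv",
    "save_summary_csv",
    "save_protocol_yaml",
    "load_protocol_yaml",
    "write_log",
]


def series_affine(protocol: AcquisitionProtocol | None) -> np.ndarray:
    """Scanner-frame affine from the protocol's fine-grid geometry (mm)."""
    if protocol is None:
        return np.eye(4)
    res = min(c.in_plane_resolution_mm for c in protocol.channels)
    aff = np.diag([res, res, protocol.slice_thickness_cm * 10.0, 1.0])
    return aff


def save_series_nifti(series: DynamicSeries, outdir: str | Path, prefix: str = "") -> list[Path]:
    """One 4D (row, col, slice, frame) NIfTI per channel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = series_affine(series.protocol)
    paths = []
    data = np.abs(series.data) if np.iscomplexobj(series.data) else series.data
    for i, name in enumerate(series.channel_names):
        img = nib.Nifti1Image(np.asarray(data[..., i], dtype=np.float32), aff)
        if series.protocol is not None:
            img.header["pixdim"][4] = series.protocol.temporal_resolution_s
        p = outdir / f"{prefix}{name}.nii"
        nib.save(img, p)
        paths.append(p)
    return paths


def load_series_nifti(
    paths: dict[str, str | Path], protocol: AcquisitionProtocol | None = None
) -> DynamicSeries:
    arrs = []
    names = []
    for name, p in paths.items():
        arrs.append(np.asarray(nib.load(str(p)).dataobj, dtype=float))
        names.append(name)
    return DynamicSeries(data=np.stack(arrs, axis=-1), channel_names=tuple(names), protocol=protocol)


def save_coil_stack(stack: CoilStack, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data, compression="gzip")
        f.create_dataset("noise_samples", data=stack.noise_samples, compression="gzip")
        f.attrs["channel_names"] = list(stack.channel_names)


def load_coil_stack(path: str | Path) -> CoilStack:
    with h5py.File(path, "r") as f:
        return CoilStack(
            data=f["data"][()],
            noise_samples=f["noise_samples"][()],
            channel_names=tuple(f.attrs["channel_names"]),
        )


def save_ground_truth(truth: PhantomGroundTruth, path: str | Path) -> None:
    """Lossless HDF5 sidecar of the phantom's ground truth."""
    with h5py.File(path, "w") as f:
        for name in ("tissue_fractions", "kpl_map", "kpg_map", "delivery_map"):
            f.create_dataset(name, data=getattr(truth, name))
        if truth.coil_sensitivities is not None:
            f.create_dataset("coil_sensitivities", data=truth.coil_sensitivities)
        if truth.coil_noise_cov is not None:
            f.create_dataset("coil_noise_cov", data=truth.coil_noise_cov)
        f.attrs["doublet_asymmetry"] = truth.doublet_asymmetry
        f.attrs["noise_sigma"] = truth.noise_sigma
        f.attrs["seed"] = truth.seed
        f.attrs["bolus"] = json.dumps(dataclasses.asdict(truth.bolus))


def load_ground_truth(path: str | Path) -> PhantomGroundTruth:
    with h5py.File(path, "r") as f:
        return PhantomGroundTruth(
            tissue_fractions=f["tissue_fractions"][()],
            kpl_map=f["kpl_map"][()],
            kpg_map=f["kpg_map"][()],
            delivery_map=f["delivery_map"][()],
            bolus=BolusParams(**json.loads(f.attrs["bolus"])),
            doublet_asymmetry=float(f.attrs["doublet_asymmetry"]),
            coil_sensitivities=f["coil_sensitivities"][()] if "coil_sensitivities" in f else None,
            coil_noise_cov=f["coil_noise_cov"][()] if "coil_noise_cov" in f else None,
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]),
        )


def save_covariance_csv(cov: NoiseCovariance, path: str | Path) -> None:
    m = cov.matrix
    df = pd.DataFrame(
        {
            "row": np.repeat(np.arange(m.shape[0]), m.shape[1]),
            "col": np.tile(np.arange(m.shape[1]), m.shape[0]),
            "real": m.real.ravel(),
            "imag": m.imag.ravel(),
        }
    )
    df.attrs["n_samples"] = cov.n_samples
    df.to_csv(path, index=False)


def save_summary_csv(summary: dict, path: str | Path) -> None:
    pd.DataFrame([summary]).to_csv(path, index=False)


def save_protocol_yaml(protocol: AcquisitionProtocol, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(protocol.to_dict(), f, sort_keys=False)


def load_protocol_yaml(path: str | Path) -> AcquisitionProtocol:
    from .protocol import MetaboliteChannel

    with open(path) as f:
        d = yaml.safe_load(f)
    channels = tuple(
        MetaboliteChannel(
            c["name"], c["in_plane_resolution_mm"], c["nominal_flip_deg"], c["chemical_shift_ppm"]
        )
        for c in d.pop("channels")
    )
    d["matrix"] = tuple(d["matrix"])
    return AcquisitionProtocol(channels=channels, **d)


def write_log(records: list[dict], path: str | Path) -> None:
    """Structured stage log as JSON lines."""
    with open(path, "w") as f:
        for rec in records:
            f.write(json.dumps(rec, default=float) + "\n")
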