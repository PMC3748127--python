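"""File formats: NIfTI volumes with JSON sidecars, CSV FIDs and force traces.

Conventions:
* image stacks -> ``<stem>.nii.gz`` + ``<stem>.json`` (echo times in ms,
  b-values in s/mm^2, direction table, phase scheme, noise sigma, seed);
* complex Dixon echoes are stored as a 5-D NIfTI with a trailing
  real/imaginary axis;
* one FID per CSV (columns t_s, real, imag) + a JSON with sweep width,
  points, reference frequency and bin timing;
* force recordings as CSV (t_s, force_mN) + JSON stimulation schedule.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom.build import GroundTruth
from .phantom.force import ForceRecording
from .phantom.mri import DiffusionVolume, MultiEchoVolume
from .pmrs.protocol import SpectrumSeries


def _affine(voxel_dims_mm: Tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_dims_mm) + [1.0])


def _write_json(path: Path, payload: Dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def save_multiecho(vol: MultiEchoVolume, stem: Path) -> None:
    stem = Path(stem)
    data = vol.data
    if np.iscomplexobj(data):
        data = np.stack([data.real, data.imag], axis=-1)
        complex_axis = True
    else:
        complex_axis = False
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), _affine(vol.voxel_dims_mm)),
             str(stem) + ".nii.gz")
    _write_json(
        stem.with_suffix(".json"),
        {
            "echo_times_ms": list(vol.echo_times_ms),
            "phase_scheme": list(vol.phase_scheme) if vol.phase_scheme else None,
            "complex_last_axis": complex_axis,
            "noise_sigma": vol.noise_sigma,
            "rng_seed": vol.rng_seed,
        },
    )


def load_multiecho(stem: Path) -> MultiEchoVolume:
    stem = Path(stem)
    img = nib.load(str(stem) + ".nii.gz")
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.asarray(img.dataobj)
    if meta.get("complex_last_axis"):
        data = data[..., 0] + 1j * data[..., 1]
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MultiEchoVolume(
        data=data,
        echo_times_ms=tuple(meta["echo_times_ms"]),
        voxel_dims_mm=dims,
        phase_scheme=tuple(meta["phase_scheme"]) if meta.get("phase_scheme") else None,
        noise_sigma=meta.get("noise_sigma", 0.0),
        rng_seed=meta.get("rng_seed"),
    )


def save_dwi(vol: DiffusionVolume, stem: Path) -> None:
    stem = Path(stem)
    nib.save(
        nib.Nifti1Image(np.asarray(vol.data, np.float64), _affine(vol.voxel_dims_mm)),
        str(stem) + ".nii.gz",
    )
    _write_json(
        stem.with_suffix(".json"),
        {
            "bvals_s_per_mm2": vol.bvals.tolist(),
            "bvecs": vol.bvecs.tolist(),
            "noise_sigma": vol.noise_sigma,
            "rng_seed": vol.rng_seed,
        },
    )


def load_dwi(stem: Path) -> DiffusionVolume:
    stem = Path(stem)
    img = nib.load(str(stem) + ".nii.gz")
    meta = json.loads(stem.with_suffix(".json").read_text())
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DiffusionVolume(
        data=np.asarray(img.dataobj),
        bvals=np.asarray(meta["bvals_s_per_mm2"], float),
        bvecs=np.asarray(meta["bvecs"], float),
        voxel_dims_mm=dims,
        noise_sigma=meta.get("noise_sigma", 0.0),
        rng_seed=meta.get("rng_seed"),
    )


def save_ground_truth(gt: GroundTruth, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(gt.voxel_dims_mm)
    nib.save(nib.Nifti1Image(gt.label_volume.astype(np.int16), aff),
             outdir / "labels.nii.gz")
    for name in ("proton_density", "fat_fraction", "t2_ms", "b0_offset_hz"):
        nib.save(nib.Nifti1Image(getattr(gt, name).astype(np.float64), aff),
                 outdir / f"{name}.nii.gz")
    nib.save(nib.Nifti1Image(gt.tensor.astype(np.float64), aff),
             outdir / "tensor.nii.gz")
    _write_json(
        outdir / "compartments.json",
        {str(lab): comp.model_dump() for lab, comp in gt.compartments.items()},
    )


def save_spectrum_series(series: SpectrumSeries, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = series.time_axis_s
    for b in range(series.n_bins):
        pd.DataFrame(
            {"t_s": t, "real": series.fids[b].real, "imag": series.fids[b].imag}
        ).to_csv(outdir / f"bin_{b:02d}.csv", index=False)
    if series.fully_relaxed is not None:
        pd.DataFrame(
            {
                "t_s": t,
                "real": series.fully_relaxed.real,
                "imag": series.fully_relaxed.imag,
            }
        ).to_csv(outdir / "fully_relaxed.csv", index=False)
    _write_json(
        outdir / "series.json",
        {
            "sweep_width_hz": series.sweep_width_hz,
            "n_points": series.n_points,
            "spectrometer_mhz": series.spectrometer_mhz,
            "bin_phase": series.bin_phase,
            "bin_start_s": series.bin_start_s.tolist(),
            "bin_width_s": series.bin_width_s.tolist(),
            "n_summed": series.n_summed.tolist(),
        },
    )


def load_spectrum_series(outdir: Path) -> SpectrumSeries:
    outdir = Path(outdir)
    meta = json.loads((outdir / "series.json").read_text())
    n_bins = len(meta["bin_phase"])
    fids = np.empty((n_bins, meta["n_points"]), dtype=complex)
    for b in range(n_bins):
        df = pd.read_csv(outdir / f"bin_{b:02d}.csv")
        fids[b] = df.real.to_numpy() + 1j * df.imag.to_numpy()
    relaxed = None
    relaxed_path = outdir / "fully_relaxed.csv"
    if relaxed_path.exists():
        df = pd.read_csv(relaxed_path)
        relaxed = df.real.to_numpy() + 1j * df.imag.to_numpy()
    return SpectrumSeries(
        fids=fids,
        bin_phase=list(meta["bin_phase"]),
        bin_start_s=np.asarray(meta["bin_start_s"], float),
        bin_width_s=np.asarray(meta["bin_width_s"], float),
        n_summed=np.asarray(meta["n_summed"], int),
        sweep_width_hz=meta["sweep_width_hz"],
        spectrometer_mhz=meta.get("spectrometer_mhz", 81.08),
        fully_relaxed=relaxed,
    )


def save_force_recording(rec: ForceRecording, stem: Path) -> None:
    stem = Path(stem)
    pd.DataFrame({"t_s": rec.t_s, "force_mN": rec.force_mN}).to_csv(
        str(stem) + ".csv", index=False
    )
    _write_json(
        stem.with_suffix(".json"),
        {"schedule": rec.schedule, "sample_rate_hz": rec.sample_rate_hz,
         "mode": rec.mode},
    )


def load_force_recording(stem: Path) -> ForceRecording:
    stem = Path(stem)
    df = pd.read_csv(str(stem) + ".csv")
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ForceRecording(
        t_s=df.t_s.to_numpy(),
        force_mN=df.force_mN.to_numpy(),
        schedule=meta["schedule"],
        sample_rate_hz=meta["sample_rate_hz"],
        mode=meta["mode"],
    )
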