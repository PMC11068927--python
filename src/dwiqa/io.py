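"""File formats: NIfTI volumes, FSL-style b-value files, marker TSVs.

All images travel as NIfTI-1 (optionally gzipped); b-values as a single
whitespace-separated line (the FSL ``.bval`` convention); acquisition
protocols as JSON; marker sets as TSV.  ADC maps are written in μm²/s as
float32 with the unit recorded in a JSON sidecar, since NIfTI itself has
no slot for ADC units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol


@dataclass
class DWISeries:
    """A 4D diffusion-weighted series with its acquisition metadata."""

    data: np.ndarray  # (x, y, z, n)
    affine: np.ndarray
    b_values: np.ndarray  # per-volume, length n
    protocol: AcquisitionProtocol

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D")
        if self.data.shape[-1] != len(self.b_values):
            raise ValueError("4th dimension must match the number of b-values")


def write_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), np.asarray(affine))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_bval(path, b_values) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_bval(path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.asarray([float(t) for t in text], dtype=float)


def read_dwi(nifti_path, bval_path, protocol_json) -> DWISeries:
    """Load a DWI series and validate it against its protocol."""
    data, affine = read_nifti(nifti_path)
    b = read_bval(bval_path)
    protocol = AcquisitionProtocol.load_json(protocol_json)
    if data.ndim != 4:
        raise ValueError("DWI NIfTI must be 4D")
    if data.shape[-1] != len(b):
        raise ValueError(
            f"{data.shape[-1]} volumes but {len(b)} b-values in {bval_path}"
        )
    if not set(np.unique(b)) <= set(protocol.b_values):
        raise ValueError("b-value file contains values absent from the protocol")
    if 0.0 not in b:
        raise ValueError("series contains no b=0 volume")
    return DWISeries(data=data, affine=affine, b_values=b, protocol=protocol)


def write_dwi(out_dir, stem: str, data_4d, affine, b_values,
              protocol: AcquisitionProtocol) -> dict:
    """Write a simulated series as NIfTI + .bval + protocol JSON; returns
    the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": out / f"{stem}.nii.gz",
        "bval": out / f"{stem}.bval",
        "protocol": out / f"{stem}_protocol.json",
    }
    write_nifti(paths["nifti"], data_4d, affine)
    write_bval(paths["bval"], b_values)
    protocol.save_json(paths["protocol"])
    return {k: str(v) for k, v in paths.items()}


def write_adc_map(out_dir, adc_map, affine, meta: dict | None = None) -> dict:
    """Write ADC (μm²/s), S0 and validity mask with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / "adc.nii.gz", np.nan_to_num(adc_map.adc), affine)
    write_nifti(out / "s0.nii.gz", np.nan_to_num(adc_map.s0), affine)
    write_nifti(out / "valid_mask.nii.gz", adc_map.valid_mask, affine, dtype=np.uint8)
    sidecar = {
        "adc_units": "um^2/s",
        "b_subset": list(adc_map.b_subset),
        "eta_sq": adc_map.eta_sq,
        "n_invalid": int((~adc_map.valid_mask).sum()),
    }
    if meta:
        sidecar.update(meta)
    (out / "adc.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar
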