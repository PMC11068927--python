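"""Off-resonance field summaries: ppm, displacement in mm, and the 95th
percentile of absolute values within a mask.

Off-resonance in Hz is field-strength dependent; dividing by the scanner
resonance frequency (×10⁶) yields ppm, a hardware-comparable inhomogeneity
measure.  Dividing by the per-pixel phase-encode bandwidth and multiplying
by the PE voxel size converts Hz to the geometric displacement in mm that
the field induces in an EPI image.
"""

from __future__ import annotations

import numpy as np

from .protocol import AcquisitionProtocol
from .synthetic import FieldMap


def _values(field) -> np.ndarray:
    return field.values if isinstance(field, FieldMap) else np.asarray(field, dtype=float)


def field_to_ppm(field_hz, resonance_hz: float) -> np.ndarray:
    """ppm = field_hz / resonance_hz × 10⁶."""
    if resonance_hz <= 0:
        raise ValueError("resonance frequency must be positive")
    return _values(field_hz) / resonance_hz * 1e6


def field_to_displacement_mm(field_hz, bw_pe_px: float, voxel_mm_pe: float) -> np.ndarray:
    """EPI displacement d_mm = field_hz / bw_pe_px × voxel_mm_pe."""
    if bw_pe_px <= 0:
        raise ValueError("bandwidth must be positive")
    if voxel_mm_pe <= 0:
        raise ValueError("voxel size must be positive")
    return _values(field_hz) / bw_pe_px * voxel_mm_pe


def p95_abs_in_mask(map_3d, mask) -> float:
    """95th percentile (linear-interpolation quantile) of |values| within a
    mask — a measure of high, locally occurring field values."""
    v = _values(map_3d)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != v.shape:
        raise ValueError("mask and map must share a shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.percentile(np.abs(v[mask]), 95))


def field_summary(field_hz, mask, protocol: AcquisitionProtocol) -> dict:
    """p95 |off-resonance| in Hz, ppm and mm within a mask."""
    hz = p95_abs_in_mask(field_hz, mask)
    return {
        "p95_hz": hz,
        "p95_ppm": hz / protocol.resonance_hz * 1e6,
        "p95_mm": hz / protocol.bw_pe_px * protocol.voxel_mm_pe,
    }
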