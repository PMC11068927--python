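"""Acquisition protocol metadata for EPI diffusion-weighted series.

The protocol carries everything the distortion and ADC analyses need to
interpret a 4D DWI stack: the diffusion weightings (b-values), the
phase-encode (PE) geometry of the EPI readout, the per-pixel bandwidth in
the PE direction (which converts off-resonance in Hz to pixel displacement),
the voxel size, and the scanner resonance frequency (which converts Hz to
ppm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Metadata of an EPI DWI acquisition.

    Parameters
    ----------
    b_values : sequence of float
        Diffusion weightings in s/mm², ascending, must contain 0.
    pe_axis : int
        Image axis (0, 1 or 2) along which phase encoding runs.
    pe_sign : int
        Polarity of the phase-encode blips, +1 or -1.  Off-resonance
        displaces signal by ``pe_sign * field_hz / bw_pe_px`` pixels.
    bw_pe_px : float
        Receiver bandwidth per pixel in the phase-encode direction, Hz/px.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    resonance_hz : float
        Scanner resonance frequency in Hz (e.g. 14.707e6 at 0.35 T,
        123.152e6 at 3 T).
    """

    b_values: tuple = ()
    pe_axis: int = 1
    pe_sign: int = 1
    bw_pe_px: float = 1352.0
    voxel_size: tuple = (3.0, 3.0, 6.0)
    resonance_hz: float = 14.707e6

    def __post_init__(self):
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if len(self.b_values) < 2:
            raise ValueError("protocol needs at least two b-values")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if 0.0 not in self.b_values:
            raise ValueError("protocol must contain b=0")
        if list(self.b_values) != sorted(self.b_values):
            raise ValueError("b-values must be ascending")
        if self.pe_axis not in (0, 1, 2):
            raise ValueError("pe_axis must be 0, 1 or 2")
        if self.pe_sign not in (1, -1):
            raise ValueError("pe_sign must be +1 or -1")
        if self.bw_pe_px <= 0:
            raise ValueError("bw_pe_px must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths in mm")
        if self.resonance_hz <= 0:
            raise ValueError("resonance_hz must be positive")

    @property
    def voxel_mm_pe(self) -> float:
        """Voxel edge length along the phase-encode axis, mm."""
        return self.voxel_size[self.pe_axis]

    def with_pe_sign(self, pe_sign: int) -> "AcquisitionProtocol":
        """Copy of the protocol with the given phase-encode polarity."""
        return AcquisitionProtocol(
            b_values=self.b_values,
            pe_axis=self.pe_axis,
            pe_sign=pe_sign,
            bw_pe_px=self.bw_pe_px,
            voxel_size=self.voxel_size,
            resonance_hz=self.resonance_hz,
        )

    def to_dict(self) -> dict:
        return {
            "b_values": list(self.b_values),
            "pe_axis": self.pe_axis,
            "pe_sign": self.pe_sign,
            "bw_pe_px": self.bw_pe_px,
            "voxel_size": list(self.voxel_size),
            "resonance_hz": self.resonance_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        missing = {"b_values", "pe_axis", "pe_sign", "bw_pe_px",
                   "voxel_size", "resonance_hz"} - set(d)
        if missing:
            raise KeyError(f"protocol JSON missing keys: {sorted(missing)}")
        return cls(
            b_values=tuple(d["b_values"]),
            pe_axis=int(d["pe_axis"]),
            pe_sign=int(d["pe_sign"]),
            bw_pe_px=float(d["bw_pe_px"]),
            voxel_size=tuple(d["voxel_size"]),
            resonance_hz=float(d["resonance_hz"]),
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path) -> "AcquisitionProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mr_linac_protocol(pe_sign: int = 1, bw_pe_px: float = 1352.0) -> AcquisitionProtocol:
    """Default low-field MR-Linac protocol: five b-values up to 800 s/mm²,
    3x3x6 mm voxels, 14.707 MHz resonance, normal bandwidth 1352 Hz/px."""
    return AcquisitionProtocol(
        b_values=(0.0, 200.0, 400.0, 600.0, 800.0),
        pe_axis=1,
        pe_sign=pe_sign,
        bw_pe_px=bw_pe_px,
        voxel_size=(3.0, 3.0, 6.0),
        resonance_hz=14.707e6,
    )


def scanner_3t_protocol(pe_sign: int = 1, bw_pe_px: float = 1352.0) -> AcquisitionProtocol:
    """Default 3 T comparison protocol: two b-values (0 and 1000 s/mm²),
    123.152 MHz resonance."""
    return AcquisitionProtocol(
        b_values=(0.0, 1000.0),
        pe_axis=1,
        pe_sign=pe_sign,
        bw_pe_px=bw_pe_px,
        voxel_size=(2.0, 2.0, 4.0),
        resonance_hz=123.152e6,
    )
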