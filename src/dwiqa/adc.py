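"""Voxelwise ADC estimation with background noise-floor correction.

Magnitude MR images have a positive noise floor: in background, the
two-channel (Rician/Rayleigh) magnitude has E[S²] = 2σ².  Low-SNR
diffusion-weighted signals are therefore biased upward, which biases the
fitted ADC downward.  The correction used here subtracts the background
second moment in quadrature:

    S' = sqrt(max(S² − η², 0)),   η² = mean background S²,

so that S'² is an (asymptotically) unbiased estimate of the squared true
signal.  Voxels whose measured S² does not exceed the noise floor carry no
usable signal and are dropped from that voxel's fit rather than clamped.

The ADC itself comes from ordinary least squares of ln S' on b:
ln S(b) = ln S0 − b · ADC·1e-6 with ADC in μm²/s and b in s/mm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import DIFFUSIVITY_SCALE


@dataclass(frozen=True)
class NoiseEstimate:
    """Background noise level: second moment of magnitude intensity."""

    eta_sq: float
    n_voxels: int
    cuboid: tuple  # ((i0, j0, k0), (si, sj, sk))

    def __post_init__(self):
        if self.eta_sq < 0:
            raise ValueError("eta_sq must be non-negative")


@dataclass
class ADCMap:
    """Voxelwise mono-exponential fit result.

    adc (μm²/s) and s0 are finite wherever ``valid_mask``; ``n_used`` counts
    the b-value samples that survived the noise-floor flagging per voxel.
    """

    adc: np.ndarray
    s0: np.ndarray
    n_used: np.ndarray
    valid_mask: np.ndarray
    b_subset: tuple = ()
    eta_sq: float = 0.0


def estimate_background_noise(volume_4d: np.ndarray, cuboid) -> NoiseEstimate:
    """Second moment of intensity in a background cuboid, pooled over all
    b-value volumes.

    ``cuboid`` is ((i0, j0, k0), (si, sj, sk)) in 0-based voxel indices.
    The caller is responsible for placing it entirely in background.
    """
    v = np.asarray(volume_4d, dtype=float)
    if v.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, b)")
    (i0, j0, k0), (si, sj, sk) = cuboid
    if min(i0, j0, k0) < 0 or min(si, sj, sk) <= 0:
        raise ValueError("cuboid indices must be non-negative with positive size")
    if i0 + si > v.shape[0] or j0 + sj > v.shape[1] or k0 + sk > v.shape[2]:
        raise ValueError("cuboid extends outside the volume")
    block = v[i0 : i0 + si, j0 : j0 + sj, k0 : k0 + sk, :]
    n = si * sj * sk
    if n < 100:
        raise ValueError("background cuboid smaller than 100 voxels is unreliable")
    return NoiseEstimate(
        eta_sq=float(np.mean(block**2)),
        n_voxels=int(n),
        cuboid=((i0, j0, k0), (si, sj, sk)),
    )


def correct_noise_floor(signal: np.ndarray, noise: NoiseEstimate):
    """Noise-floor-corrected signal and a flag mask.

    Returns (S', flagged) with S' = sqrt(max(S² − η², 0)); flagged marks
    samples with S² ≤ η² that must be excluded from fitting.
    """
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("magnitude signal must be non-negative")
    sq = s**2 - noise.eta_sq
    flagged = sq <= 0
    return np.sqrt(np.clip(sq, 0.0, None)), flagged


def fit_adc(
    data_4d: np.ndarray,
    b_values,
    b_subset=None,
    noise: NoiseEstimate | None = None,
) -> ADCMap:
    """Voxelwise log-linear ADC fit.

    Parameters
    ----------
    data_4d : array (x, y, z, n)
        Magnitude DWI stack.  Repeated b-values (e.g. the two phase-encode
        polarities) are allowed: replicates are averaged after noise-floor
        correction, before the log.
    b_values : sequence of float
        b-value of each volume along the 4th axis, s/mm².
    b_subset : sequence of float, optional
        The b-values to fit on (must include 0); default all.
    noise : NoiseEstimate, optional
        Background noise level; when given, the noise-floor correction is
        applied and sub-floor samples are dropped per voxel.

    Returns
    -------
    ADCMap
        ADC in μm²/s (slope) and S0 (intercept); voxels with fewer than two
        usable b-values are invalid.
    """
    v = np.asarray(data_4d, dtype=float)
    b_all = np.asarray(list(b_values), dtype=float)
    if v.ndim != 4 or v.shape[-1] != len(b_all):
        raise ValueError("4th dimension must match the number of b-values")
    if b_subset is None:
        b_subset = np.unique(b_all)
    b_subset = np.asarray(sorted(set(float(b) for b in b_subset)), dtype=float)
    if len(b_subset) < 2:
        raise ValueError("need at least two distinct b-values")
    if 0.0 not in b_subset:
        raise ValueError("b_subset must contain b=0")
    if not set(b_subset) <= set(b_all):
        raise ValueError("b_subset must be a subset of the acquired b-values")

    if noise is not None:
        corrected, flagged = correct_noise_floor(v, noise)
        eta_sq = noise.eta_sq
    else:
        corrected, flagged = v, np.zeros(v.shape, dtype=bool)
        eta_sq = 0.0

    # average same-b replicates of the corrected signal
    means = []
    for b in b_subset:
        sel = b_all == b
        means.append(corrected[..., sel].mean(axis=-1))
    s_mean = np.stack(means, axis=-1)

    usable = s_mean > 0
    n_used = usable.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(usable, np.log(np.where(usable, s_mean, 1.0)), 0.0)

    w = usable.astype(float)
    bb = b_subset.reshape((1, 1, 1, -1))
    sw = w.sum(axis=-1)
    sb = (w * bb).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sbb = (w * bb * bb).sum(axis=-1)
    sby = (w * bb * y).sum(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = sw * sbb - sb * sb
        slope = (sw * sby - sb * sy) / denom
        intercept = (sy - slope * sb) / sw

    valid = (n_used >= 2) & (denom > 0) & np.isfinite(slope)
    adc = np.where(valid, -slope / DIFFUSIVITY_SCALE, np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)

    return ADCMap(
        adc=adc,
        s0=s0,
        n_used=n_used.astype(int),
        valid_mask=valid,
        b_subset=tuple(b_subset),
        eta_sq=float(eta_sq),
    )


def temperature_correct_reference(vial_id, temp_c: float, calibration_table: dict) -> float:
    """Reference ADC of a vial at the acquisition temperature.

    ``calibration_table`` maps vial id -> {temperature °C: ADC μm²/s}
    (as supplied by the phantom manual).  Values are linearly interpolated
    between the bracketing tabulated temperatures; temperatures outside the
    tabulated range raise.
    """
    if vial_id not in calibration_table:
        raise KeyError(f"no calibration entries for vial {vial_id!r}")
    entries = calibration_table[vial_id]
    temps = np.asarray(sorted(float(t) for t in entries), dtype=float)
    vals = np.asarray([float(entries[t]) for t in sorted(entries, key=float)])
    if not (temps[0] <= temp_c <= temps[-1]):
        raise ValueError(
            f"temperature {temp_c} °C outside the calibrated range "
            f"[{temps[0]}, {temps[-1]}]"
        )
    return float(np.interp(temp_c, temps, vals))
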