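"""Synthetic phantoms, brain-like scenes, DWI signal simulation and EPI warps.

This module generates every input the QA pipeline consumes:

* a multi-vial diffusion phantom with calibrated ADC values,
* a 3D grid phantom (orthogonal beams) whose beam intersections serve as
  distortion markers,
* a three-compartment brain-like scene (CSF / gray matter / white matter)
  with optional bi-exponential (IVIM-like) signal in CSF,
* mono-/bi-exponential diffusion signal evaluation,
* Rician (two-channel magnitude) noise,
* susceptibility-like off-resonance fields and the EPI warp they induce
  along the phase-encode direction.

Conventions: voxel indices are 0-based; world coordinates in mm follow the
image affine, whose origin is placed so that the volume center sits at
world (0, 0, 0).  Diffusivities are in μm²/s and b-values in s/mm², so the
signal exponent is ``b * D * 1e-6`` (1000 μm²/s = 1.0e-3 mm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .markers import MarkerSet
from .protocol import AcquisitionProtocol


class GeometryError(ValueError):
    """Requested synthetic geometry does not fit the voxel grid."""


DIFFUSIVITY_SCALE = 1e-6  # μm²/s -> mm²/s, so that b [s/mm²] · D is unitless


@dataclass(frozen=True)
class TissueParams:
    """Signal model parameters of one compartment.

    S(b) = S0 * ( f * exp(-b * D_star * 1e-6) + (1 - f) * exp(-b * D * 1e-6) )

    with D and D_star in μm²/s and b in s/mm².  ``f`` is the fast
    (pseudo-diffusion / perfusion-like) volume fraction; f = 0 gives the
    mono-exponential model.
    """

    s0: float
    d: float
    f: float = 0.0
    d_star: float = 0.0

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("diffusivity D must be non-negative")
        if not (0.0 <= self.f < 1.0):
            raise ValueError("fast fraction f must lie in [0, 1)")
        if self.f > 0 and self.d_star < self.d:
            raise ValueError("pseudo-diffusion D* must be >= D when f > 0")


@dataclass
class Scene:
    """A labeled digital object: label map + per-label signal parameters."""

    label_map: np.ndarray
    tissue_params: dict
    affine: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        labels = set(np.unique(self.label_map)) - {0}
        missing = labels - set(self.tissue_params)
        if missing:
            raise ValueError(f"labels without tissue parameters: {sorted(missing)}")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def world_grid(self):
        """Per-axis 1D world coordinates (mm) of voxel centers."""
        return [
            self.affine[ax, ax] * np.arange(self.label_map.shape[ax]) + self.affine[ax, 3]
            for ax in range(3)
        ]

    def param_map(self, name: str) -> np.ndarray:
        """Voxelwise map of one tissue parameter (0 in background)."""
        out = np.zeros(self.label_map.shape, dtype=float)
        for lab, p in self.tissue_params.items():
            out[self.label_map == lab] = getattr(p, name)
        return out


@dataclass
class FieldMap:
    """Off-resonance field in Hz on an image grid."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map must be finite everywhere")


def centered_affine(shape, voxel_size) -> np.ndarray:
    """Diagonal affine placing the volume center at world origin."""
    shape = np.asarray(shape)
    voxel = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel)
    aff[:3, 3] = -(shape - 1) / 2.0 * voxel
    return aff


def _world_coords(shape, affine):
    return [
        affine[ax, ax] * np.arange(shape[ax]) + affine[ax, 3] for ax in range(3)
    ]


def cylinder_mask(shape, affine, center_mm, radius_mm, height_mm, axis: int = 2) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside a cylinder."""
    xs = _world_coords(shape, affine)
    rel = [xs[ax] - center_mm[ax] for ax in range(3)]
    plane = [ax for ax in range(3) if ax != axis]
    sq = (
        rel[plane[0]].reshape([-1 if a == plane[0] else 1 for a in range(3)]) ** 2
        + rel[plane[1]].reshape([-1 if a == plane[1] else 1 for a in range(3)]) ** 2
    )
    along = np.abs(rel[axis]).reshape([-1 if a == axis else 1 for a in range(3)])
    return np.broadcast_to(sq <= radius_mm**2, shape) & np.broadcast_to(
        along <= height_mm / 2.0, shape
    )


# --------------------------------------------------------------------------
# Vial phantom
# --------------------------------------------------------------------------

DEFAULT_VIAL_ADCS = (400.0, 1000.0, 1600.0, 2020.0)  # calibrated at 20 °C
DEFAULT_VOI_RADIUS_MM = 6.0
DEFAULT_VOI_HEIGHT_MM = 39.0


def make_vial_phantom(
    grid_shape=(32, 32, 12),
    voxel_size=(3.0, 3.0, 6.0),
    vial_adcs=DEFAULT_VIAL_ADCS,
    vial_radius_mm: float = 9.0,
    vial_height_mm: float = 54.0,
    s0: float = 1000.0,
) -> Scene:
    """Cylindrical-vial ADC phantom.

    Vials (one integer label each, background 0 with zero signal) are placed
    on a circle in the axial plane, axes along z.  Defaults give four vials
    with the calibrated diffusivities 400 / 1000 / 1600 / 2020 μm²/s.

    Raises
    ------
    GeometryError
        If vials would overlap or extend outside the grid.
    """
    vial_adcs = list(vial_adcs)
    if not (1 <= len(vial_adcs) <= 8):
        raise GeometryError("supports 1 to 8 vials")
    shape = tuple(int(s) for s in grid_shape)
    affine = centered_affine(shape, voxel_size)
    fov = np.asarray(shape) * np.asarray(voxel_size, dtype=float)

    n = len(vial_adcs)
    gap = 4.0  # mm clearance between vials and to the volume edge
    if n == 1:
        centers = [(0.0, 0.0)]
    else:
        ring = max(
            (2 * vial_radius_mm + gap) / (2 * np.sin(np.pi / n)), vial_radius_mm + gap
        )
        ang = 2 * np.pi * np.arange(n) / n + np.pi / 4
        centers = [(ring * np.cos(a), ring * np.sin(a)) for a in ang]

    for cx, cy in centers:
        if (
            abs(cx) + vial_radius_mm + gap > fov[0] / 2
            or abs(cy) + vial_radius_mm + gap > fov[1] / 2
            or vial_height_mm > fov[2]
        ):
            raise GeometryError("vials do not fit inside the grid")

    label_map = np.zeros(shape, dtype=np.int16)
    params = {}
    vial_centers = {}
    for idx, ((cx, cy), adc) in enumerate(zip(centers, vial_adcs), start=1):
        mask = cylinder_mask(
            shape, affine, (cx, cy, 0.0), vial_radius_mm, vial_height_mm, axis=2
        )
        if np.any(label_map[mask] != 0):
            raise GeometryError("vials overlap at the requested radius")
        label_map[mask] = idx
        params[idx] = TissueParams(s0=float(s0), d=float(adc))
        vial_centers[idx] = (cx, cy, 0.0)

    return Scene(
        label_map=label_map,
        tissue_params=params,
        affine=affine,
        meta={"kind": "vial_phantom", "vial_centers": vial_centers},
    )


def vial_voi_masks(
    scene: Scene,
    radius_mm: float = DEFAULT_VOI_RADIUS_MM,
    height_mm: float = DEFAULT_VOI_HEIGHT_MM,
) -> dict:
    """Per-vial cylindrical analysis VOIs (default radius 6 mm, height 39 mm)
    centered on each vial axis."""
    centers = scene.meta.get("vial_centers")
    if centers is None:
        raise ValueError("scene does not carry vial centers")
    return {
        lab: cylinder_mask(
            scene.label_map.shape, scene.affine, c, radius_mm, height_mm, axis=2
        )
        for lab, c in centers.items()
    }


# --------------------------------------------------------------------------
# Grid phantom
# --------------------------------------------------------------------------


def _axis_coverage(x: np.ndarray, voxel: float, intervals) -> np.ndarray:
    """Fraction of each voxel (centers x, width voxel) covered by a union of
    disjoint 1D intervals — partial-volume rasterization along one axis."""
    cov = np.zeros_like(x)
    for lo, hi in intervals:
        overlap = np.minimum(x + voxel / 2.0, hi) - np.maximum(x - voxel / 2.0, lo)
        cov += np.clip(overlap / voxel, 0.0, 1.0)
    return np.clip(cov, 0.0, 1.0)


def beam_union_image(xs, voxel_size, line_positions, thickness_mm, extents_mm) -> np.ndarray:
    """Partial-volume image of three orthogonal beam families.

    ``line_positions[ax]`` holds the beam center coordinates transverse to
    axis ``ax``; each beam has a square cross-section of side
    ``thickness_mm`` and runs over ``|coordinate| <= extents_mm[ax] / 2``
    along its axis.  Per-voxel coverages combine by the inclusion–exclusion
    soft union, so edge voxels get fractional intensity exactly as a real
    acquisition's partial-volume effect would produce.
    """
    half_t = thickness_mm / 2.0

    def _b(v, ax):
        return v.reshape([-1 if a == ax else 1 for a in range(3)])

    trans = []  # transverse coverage per axis
    along = []  # in-extent coverage per axis
    for ax in range(3):
        ivals = [(p - half_t, p + half_t) for p in line_positions[ax]]
        trans.append(_axis_coverage(xs[ax], voxel_size[ax], ivals))
        e = extents_mm[ax] / 2.0
        along.append(_axis_coverage(xs[ax], voxel_size[ax], [(-e, e)]))

    a = _b(along[0], 0) * _b(trans[1], 1) * _b(trans[2], 2)
    b = _b(trans[0], 0) * _b(along[1], 1) * _b(trans[2], 2)
    c = _b(trans[0], 0) * _b(trans[1], 1) * _b(along[2], 2)
    return a + b + c - a * b - a * c - b * c + a * b * c


@dataclass
class GridPhantom:
    """Rasterized beam image plus the theoretical marker lattice."""

    image: np.ndarray
    markers: MarkerSet
    affine: np.ndarray
    spacing_mm: float
    beam_thickness_mm: float


def make_grid_phantom(
    spacing_mm: float = 25.0,
    beam_thickness_mm: float = 6.0,
    fov_mm=(100.0, 100.0, 100.0),
    voxel_size=(1.5, 1.5, 1.5),
    margin_mm: float = 10.0,
    beam_overhang_mm: float = 7.5,
    intensity: float = 1000.0,
) -> GridPhantom:
    """Orthogonal-beam grid phantom.

    Beams of square cross-section (``beam_thickness_mm``) run along each
    axis at every lattice line, ``spacing_mm`` apart.  The lattice spans
    ``fov_mm``; beams overhang the outermost lattice planes by
    ``beam_overhang_mm`` so that every intersection — including the outer
    shell — is a complete three-axis cross (otherwise template matching is
    systematically biased inward at the boundary).  Beam intersections
    form the theoretical markers; their world coordinates are exact
    multiples of the spacing relative to the grid center, and the set is
    sorted lexicographically by grid index.  Rasterization uses
    partial-volume (box-overlap) edge coverage.
    """
    if spacing_mm <= beam_thickness_mm:
        raise GeometryError("spacing must exceed beam thickness")
    voxel = np.asarray(voxel_size, dtype=float)
    if np.any(voxel >= beam_thickness_mm):
        raise GeometryError("voxel size must be smaller than the beam thickness")
    fov = np.asarray(fov_mm, dtype=float)
    n_lines = np.floor(fov / spacing_mm).astype(int) + 1
    if np.any(n_lines < 3):
        raise GeometryError("need at least 3 grid lines per axis")

    shape = tuple(int(np.ceil((f + 2 * margin_mm) / v)) for f, v in zip(fov, voxel))
    affine = centered_affine(shape, voxel)
    xs = _world_coords(shape, affine)

    # lattice line positions, centered on the volume
    lines = [
        (np.arange(n) - (n - 1) / 2.0) * spacing_mm for n in n_lines
    ]
    image = intensity * beam_union_image(
        xs, voxel, lines, beam_thickness_mm, fov + 2 * beam_overhang_mm
    )

    idx = [
        (i, j, k)
        for i in range(n_lines[0])
        for j in range(n_lines[1])
        for k in range(n_lines[2])
    ]
    grid_index = np.asarray(idx)
    pos = np.stack(
        [lines[ax][grid_index[:, ax]] for ax in range(3)], axis=1
    )
    markers = MarkerSet(
        ids=np.arange(len(idx)), grid_index=grid_index, pos_mm=pos
    )
    return GridPhantom(
        image=image,
        markers=markers,
        affine=affine,
        spacing_mm=spacing_mm,
        beam_thickness_mm=beam_thickness_mm,
    )


# --------------------------------------------------------------------------
# Brain-like scene
# --------------------------------------------------------------------------

BRAIN_LABELS = {"csf": 1, "gm": 2, "wm": 3}

DEFAULT_BRAIN_PARAMS = {
    # literature-typical diffusivities; CSF optionally bi-exponential
    "csf": TissueParams(s0=1000.0, d=3000.0),
    "gm": TissueParams(s0=800.0, d=900.0),
    "wm": TissueParams(s0=700.0, d=700.0),
}


def make_brain_scene(
    grid_shape=(48, 48, 20),
    voxel_size=(3.0, 3.0, 6.0),
    tissue_params: dict | None = None,
) -> Scene:
    """Three-compartment nested-ellipsoid head: WM core, GM shell, CSF rim.

    The label map doubles as the set of tissue VOIs (CSF=1, GM=2, WM=3).
    """
    params = dict(DEFAULT_BRAIN_PARAMS)
    if tissue_params:
        params.update(tissue_params)
    missing = {"csf", "gm", "wm"} - set(params)
    if missing:
        raise ValueError(f"missing tissue parameters: {sorted(missing)}")

    shape = tuple(int(s) for s in grid_shape)
    affine = centered_affine(shape, voxel_size)
    fov = np.asarray(shape) * np.asarray(voxel_size, dtype=float)
    semi = fov / 2.0
    # outer CSF ellipsoid at 90% of the half-extent, GM at 78%, WM at 58%
    fractions = {"csf": 0.90, "gm": 0.78, "wm": 0.58}
    if any(f * min(semi) < 2 * max(voxel_size) for f in fractions.values()):
        raise GeometryError("grid too small for nested ellipsoids")

    xs = _world_coords(shape, affine)

    def ellipsoid(frac):
        r = semi * frac
        q = sum(
            (xs[ax].reshape([-1 if a == ax else 1 for a in range(3)]) / r[ax]) ** 2
            for ax in range(3)
        )
        return q <= 1.0

    label_map = np.zeros(shape, dtype=np.int16)
    label_map[ellipsoid(fractions["csf"])] = BRAIN_LABELS["csf"]
    label_map[ellipsoid(fractions["gm"])] = BRAIN_LABELS["gm"]
    label_map[ellipsoid(fractions["wm"])] = BRAIN_LABELS["wm"]

    return Scene(
        label_map=label_map,
        tissue_params={BRAIN_LABELS[name]: params[name] for name in BRAIN_LABELS},
        affine=affine,
        meta={"kind": "brain", "labels": dict(BRAIN_LABELS)},
    )


# --------------------------------------------------------------------------
# Signal simulation and noise
# --------------------------------------------------------------------------


def simulate_signal(scene: Scene, b: float) -> np.ndarray:
    """Noise-free magnitude signal at diffusion weighting ``b`` (s/mm²)."""
    if b < 0:
        raise ValueError("b must be non-negative")
    s0 = scene.param_map("s0")
    d = scene.param_map("d")
    f = scene.param_map("f")
    d_star = scene.param_map("d_star")
    slow = np.exp(-b * d * DIFFUSIVITY_SCALE)
    fast = np.exp(-b * d_star * DIFFUSIVITY_SCALE)
    return s0 * (f * fast + (1.0 - f) * slow)


def add_rician_noise(volume: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise.

    out = sqrt((v + g1)² + g2²) with g1, g2 ~ N(0, σ²) i.i.d., the standard
    two-channel magnitude noise model.  In background (v = 0) this is
    Rayleigh with mean σ√(π/2) and second moment 2σ².
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(volume, dtype=float).copy()
    rng = np.random.default_rng(rng)
    v = np.asarray(volume, dtype=float)
    g1 = rng.normal(0.0, sigma, size=v.shape)
    g2 = rng.normal(0.0, sigma, size=v.shape)
    return np.sqrt((v + g1) ** 2 + g2**2)


# --------------------------------------------------------------------------
# EPI warp
# --------------------------------------------------------------------------


def _interp_along_last(v: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Linear interpolation of v at (fractional) sample positions s along
    the last axis, zero outside the array."""
    n = v.shape[-1]
    i0 = np.floor(s).astype(int)
    w = s - i0
    i1 = i0 + 1
    valid0 = (i0 >= 0) & (i0 <= n - 1)
    valid1 = (i1 >= 0) & (i1 <= n - 1)
    v0 = np.take_along_axis(v, np.clip(i0, 0, n - 1), axis=-1)
    v1 = np.take_along_axis(v, np.clip(i1, 0, n - 1), axis=-1)
    return (1.0 - w) * v0 * valid0 + w * v1 * valid1


class WarpError(ValueError):
    """Displacement exceeds the image extent."""


def apply_epi_warp(
    volume: np.ndarray,
    field,
    protocol: AcquisitionProtocol,
    pe_sign: int | None = None,
) -> np.ndarray:
    """Distort a volume by an off-resonance field, EPI-style.

    Signal at true position y appears at y + d(y) pixels along the
    phase-encode axis, with d = pe_sign * field_hz / bw_pe_px.  Implemented
    as a pull-back: out(x) = J(x) · v(x − d(x)) with the Jacobian
    J = ∂(x − d)/∂x evaluated by central differences, which conserves
    line integrals along PE to first order in the field's smoothness.
    """
    f = field.values if isinstance(field, FieldMap) else np.asarray(field, dtype=float)
    v = np.asarray(volume, dtype=float)
    if f.shape != v.shape:
        raise ValueError("field and volume must share a grid")
    sign = protocol.pe_sign if pe_sign is None else pe_sign
    if sign not in (1, -1):
        raise ValueError("pe_sign must be +1 or -1")
    ax = protocol.pe_axis
    d = sign * f / protocol.bw_pe_px  # pixels
    n = v.shape[ax]
    if np.max(np.abs(d)) > n:
        raise WarpError("displacement exceeds the image extent along PE")

    v_m = np.moveaxis(v, ax, -1)
    d_m = np.moveaxis(d, ax, -1)
    pos = np.arange(n, dtype=float)
    s = pos - d_m
    jac = 1.0 - np.gradient(d_m, axis=-1)
    out = np.clip(jac, 0.0, None) * _interp_along_last(v_m, s)
    return np.moveaxis(out, -1, ax)


def make_susceptibility_field(
    grid_shape,
    voxel_size,
    amplitude_hz: float,
    smooth_scale_mm: float = 20.0,
    blob: dict | None = None,
    seed=None,
    mask: np.ndarray | None = None,
) -> FieldMap:
    """Smooth random off-resonance field plus an optional positive blob.

    The random component is white noise smoothed at ``smooth_scale_mm``,
    zero-meaned over the mask (or the whole volume) and scaled so its
    extreme magnitude equals ``amplitude_hz``.  ``blob`` adds a localized
    Gaussian bump: ``{"center_mm": (x,y,z), "sigma_mm": s,
    "amplitude_hz": a}`` — the kind of focal off-resonance seen near
    air-tissue interfaces.  The total field never exceeds
    amplitude_hz + blob amplitude in magnitude.
    """
    if amplitude_hz < 0:
        raise ValueError("amplitude must be non-negative")
    shape = tuple(int(s) for s in grid_shape)
    voxel = np.asarray(voxel_size, dtype=float)
    affine = centered_affine(shape, voxel)

    values = np.zeros(shape, dtype=float)
    if amplitude_hz > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=shape)
        sig = smooth_scale_mm / voxel
        values = gaussian_filter(noise, sigma=sig)
        sel = mask if mask is not None else np.ones(shape, dtype=bool)
        values -= values[sel].mean()
        peak = np.max(np.abs(values[sel]))
        if peak > 0:
            values *= amplitude_hz / peak
        if mask is not None:
            values = values * mask

    if blob is not None:
        xs = _world_coords(shape, affine)
        c = blob["center_mm"]
        s2 = 2.0 * float(blob["sigma_mm"]) ** 2
        q = sum(
            (xs[ax].reshape([-1 if a == ax else 1 for a in range(3)]) - c[ax]) ** 2
            for ax in range(3)
        )
        values = values + float(blob["amplitude_hz"]) * np.exp(-q / s2)

    return FieldMap(values=values, affine=affine)


# --------------------------------------------------------------------------
# Full acquisition simulation
# --------------------------------------------------------------------------


def acquire_dwi(
    scene: Scene,
    protocol: AcquisitionProtocol,
    snr_b0: float | None,
    seed,
    field: FieldMap | None = None,
    pe_signs=(1, -1),
) -> dict:
    """Simulate a full DWI acquisition of a scene.

    For each phase-encode polarity, every b-value volume is computed,
    optionally EPI-warped by the off-resonance field, and corrupted with
    Rician noise at SNR(b=0) = max-S0 / σ.  ``snr_b0=None`` disables noise.

    Returns a dict mapping pe_sign -> 4D array (x, y, z, b).
    """
    rng = np.random.default_rng(seed)
    s0_ref = max(p.s0 for p in scene.tissue_params.values())
    sigma = 0.0 if snr_b0 is None else s0_ref / float(snr_b0)
    out = {}
    clean = [simulate_signal(scene, b) for b in protocol.b_values]
    for sign in pe_signs:
        vols = []
        for vol in clean:
            if field is not None:
                vol = apply_epi_warp(vol, field, protocol, pe_sign=sign)
            if sigma > 0:
                vol = add_rician_noise(vol, sigma, rng)
            vols.append(vol)
        out[sign] = np.stack(vols, axis=-1)
    return out
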