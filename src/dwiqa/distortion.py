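"""Grid-phantom geometric distortion quantification.

Beam intersections of the grid phantom are located in an image by
normalized cross-correlation against a cross-shaped template, refined to
subvoxel precision by separable quadratic peak interpolation.  The detected
set is rigidly referenced to the theoretical lattice via a Procrustes fit
restricted to the central 3×3×3 markers (so that global positioning does
not count as distortion), and distortion is the per-marker Euclidean
distance to the reference, summarized as mean and maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .markers import MarkerSet, match_by_index


class RegistrationError(ValueError):
    """Point-set registration is under-determined or degenerate."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass
class DistortionReport:
    """Per-marker distortion distances and their summary."""

    per_marker_mm: np.ndarray
    mean_mm: float
    max_mm: float
    n_detected: int
    n_reference: int
    marker_ids: np.ndarray | None = None

    @classmethod
    def from_distances(cls, d, n_detected, n_reference, marker_ids=None):
        d = np.asarray(d, dtype=float)
        return cls(
            per_marker_mm=d,
            mean_mm=float(d.mean()),
            max_mm=float(d.max()),
            n_detected=int(n_detected),
            n_reference=int(n_reference),
            marker_ids=None if marker_ids is None else np.asarray(marker_ids),
        )


def make_cross_template(
    beam_thickness_mm: float, voxel_size, arm_length_mm: float = 15.0
) -> np.ndarray:
    """Three-axis cross template matching the grid-beam geometry.

    The template is the union of three orthogonal square-section boxes
    (side ``beam_thickness_mm``, length ``arm_length_mm``) rasterized at
    the image resolution with partial-volume (box-overlap) edge coverage —
    the same rasterization the synthetic grid uses — centered on the
    template's central voxel.
    """
    if arm_length_mm <= beam_thickness_mm:
        raise ValueError("arm length must exceed the beam thickness")
    from .synthetic import beam_union_image

    voxel = np.asarray(voxel_size, dtype=float)
    shape = tuple(
        int(2 * np.floor((arm_length_mm / 2.0) / v) + 1) for v in voxel
    )
    xs = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel)
    ]
    return beam_union_image(
        xs, voxel, [(0.0,), (0.0,), (0.0,)], beam_thickness_mm,
        (arm_length_mm, arm_length_mm, arm_length_mm),
    )


def _quadratic_offset(ym, y0, yp) -> float:
    """Subvoxel offset of a quadratic through three equidistant samples."""
    denom = ym - 2.0 * y0 + yp
    if denom >= 0:  # not a proper maximum
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_markers(
    image: np.ndarray,
    affine: np.ndarray,
    template: np.ndarray,
    approx: MarkerSet,
    search_radius_mm: float = 12.5,
    min_score: float = 0.5,
) -> MarkerSet:
    """Template-match grid markers near their expected positions.

    For each marker in ``approx`` the normalized cross-correlation of the
    template is evaluated in a neighborhood of radius ``search_radius_mm``
    (half the grid spacing by default) around the expected position.  The
    NCC peak gives the marker position, refined per axis by quadratic
    interpolation of the peak's neighbors.  Markers whose peak NCC falls
    below ``min_score`` — or whose neighborhood has no intensity variation —
    are reported missing (NaN position, NaN score).
    """
    img = np.asarray(image, dtype=float)
    if any(ts > s for ts, s in zip(template.shape, img.shape)):
        raise ValueError("template larger than image")
    inv = np.linalg.inv(affine)
    voxel = np.abs(np.diag(affine)[:3])
    radius_vox = np.maximum(np.ceil(search_radius_mm / voxel).astype(int), 2)
    half_t = [ts // 2 for ts in template.shape]

    pos_out = np.full((len(approx), 3), np.nan)
    score_out = np.full(len(approx), np.nan)

    for m in range(len(approx)):
        center = inv[:3, :3] @ approx.pos_mm[m] + inv[:3, 3]
        c = np.round(center).astype(int)
        lo = [max(c[a] - radius_vox[a] - half_t[a], 0) for a in range(3)]
        hi = [min(c[a] + radius_vox[a] + half_t[a] + 1, img.shape[a]) for a in range(3)]
        window = img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if any(ws < ts for ws, ts in zip(window.shape, template.shape)):
            continue
        if window.std() == 0:
            continue
        resp = match_template(window, template, pad_input=True)
        # restrict the peak search to the requested neighborhood
        inner_lo = [max(c[a] - radius_vox[a], lo[a]) - lo[a] for a in range(3)]
        inner_hi = [min(c[a] + radius_vox[a] + 1, hi[a]) - lo[a] for a in range(3)]
        sub = resp[
            inner_lo[0] : inner_hi[0],
            inner_lo[1] : inner_hi[1],
            inner_lo[2] : inner_hi[2],
        ]
        if sub.size == 0:
            continue
        peak = np.unravel_index(np.argmax(sub), sub.shape)
        score = float(sub[peak])
        if not np.isfinite(score) or score < min_score:
            continue
        pk = [peak[a] + inner_lo[a] for a in range(3)]
        frac = np.zeros(3)
        for a in range(3):
            if 0 < pk[a] < resp.shape[a] - 1:
                idx_m = tuple(pk[:a] + [pk[a] - 1] + pk[a + 1 :])
                idx_p = tuple(pk[:a] + [pk[a] + 1] + pk[a + 1 :])
                frac[a] = _quadratic_offset(resp[idx_m], resp[tuple(pk)], resp[idx_p])
        vox = np.array(lo, dtype=float) + np.asarray(pk, dtype=float) + frac
        pos_out[m] = affine[:3, :3] @ vox + affine[:3, 3]
        score_out[m] = score

    return MarkerSet(
        ids=approx.ids.copy(),
        grid_index=approx.grid_index.copy(),
        pos_mm=pos_out,
        score=score_out,
    )


def rigid_procrustes(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid alignment of matched point sets.

    Finds R (rotation, det +1) and t minimizing Σ‖R·m + t − f‖² via the
    SVD of the cross-covariance (Kabsch construction), with the reflection
    corrected by flipping the smallest singular direction.  No scaling.
    """
    m = np.asarray(moving, dtype=float)
    f = np.asarray(fixed, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise RegistrationError("point sets must both be (n, 3)")
    if len(m) < 3:
        raise RegistrationError("need at least 3 matched pairs")
    mc = m - m.mean(axis=0)
    fc = f - f.mean(axis=0)
    h = mc.T @ fc
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise RegistrationError("points are collinear; rotation is ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = f.mean(axis=0) - r @ m.mean(axis=0)
    return RigidTransform(rotation=r, translation=t)


def marker_distortion(
    detected: MarkerSet,
    reference: MarkerSet,
    central_selection: np.ndarray | None = None,
) -> DistortionReport:
    """Distortion of detected markers relative to the theoretical lattice.

    The rigid transform is fit on the central markers only (default: the
    3×3×3 block by grid index), then applied to all detected markers; the
    report contains the Euclidean distances of the transformed detections
    to their reference positions, over detected (non-missing) markers.
    """
    ia, ib = match_by_index(detected, reference)
    if len(ia) == 0:
        raise RegistrationError("no markers shared between detected and reference")
    det_pos = detected.pos_mm[ia]
    ref_pos = reference.pos_mm[ib]
    found = np.isfinite(det_pos).all(axis=1)

    if central_selection is None:
        central_selection = reference.central_block(3)
    central = np.asarray(central_selection)[ib] & found
    if central.sum() < 3:
        raise RegistrationError("fewer than 3 central markers detected")

    xform = rigid_procrustes(det_pos[central], ref_pos[central])
    aligned = xform.apply(det_pos[found])
    dists = np.linalg.norm(aligned - ref_pos[found], axis=1)
    return DistortionReport.from_distances(
        dists,
        n_detected=int(found.sum()),
        n_reference=len(reference),
        marker_ids=detected.ids[ia][found],
    )


def scenario_summary(reports) -> tuple[float, float]:
    """Scenario-level distortion: arithmetic means of the per-acquisition
    mean and maximum distortions."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    mean_mm = float(np.mean([r.mean_mm for r in reports]))
    max_mm = float(np.mean([r.max_mm for r in reports]))
    return mean_mm, max_mm


def grid_manufacturing_qc(
    hi_res_image: np.ndarray,
    affine: np.ndarray,
    reference: MarkerSet,
    beam_thickness_mm: float = 6.0,
    min_score: float = 0.5,
    search_radius_mm: float = 12.5,
) -> DistortionReport:
    """Manufacturing-accuracy check of the physical grid on a high-resolution
    (CT-like) image: same detection + referencing pipeline, whose residuals
    bound the accuracy of the theoretical marker positions."""
    voxel = np.abs(np.diag(affine)[:3])
    template = make_cross_template(beam_thickness_mm, voxel)
    detected = detect_markers(
        hi_res_image,
        affine,
        template,
        approx=reference,
        search_radius_mm=search_radius_mm,
        min_score=min_score,
    )
    return marker_distortion(detected, reference)


def report_frame(report: DistortionReport) -> pd.DataFrame:
    """Per-marker table of a distortion report."""
    return pd.DataFrame(
        {
            "id": report.marker_ids
            if report.marker_ids is not None
            else np.arange(len(report.per_marker_mm)),
            "distance_mm": report.per_marker_mm,
        }
    )
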