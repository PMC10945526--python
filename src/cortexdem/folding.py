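"""Folding-orientation fields and alignment tests against expression gradients.

The orientation of cortical folds is estimated from the gradients of sulcal
depth and curvature: their per-vertex axial second-moment tensors are summed
(sulcal-depth gradients orient fold walls, curvature gradients orient fundi
and crowns), the tensor components smoothed to propagate orientation into
plateaus, and the leading eigenvector taken. Because fold direction has no
sign, everything here is axial: angles between fields live in [0, 90] and a
uniform angle distribution has zero skewness, so alignment (angles piling up
near zero) shows up as positive skew.

Rather than flattening the cortex globally, orientations are compared in
per-vertex tangent planes and transported through spin rotations; on
developable patches this is identical to comparison after flattening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .spin import SpinEnsemble, _pvalue, angle_between_fields, spin_tangent_field
from .surface import CorticalSurface, TangentField, compute_gradient, smooth_map

__all__ = [
    "AngleDistribution",
    "fold_orientation",
    "angle_between",
    "alignment_skew_test",
    "roi_axis_alignment",
]


@dataclass
class AngleDistribution:
    """Axial angles in [0, 90] with their Fisher-Pearson adjusted skewness."""

    angles: np.ndarray
    valid: np.ndarray
    skewness: float


def _axial_tensor(field: TangentField) -> np.ndarray:
    """(V, 3) independent components (xx, xy, yy) of g g^T per vertex."""
    c = field.coeffs
    return np.column_stack([c[:, 0] ** 2, c[:, 0] * c[:, 1], c[:, 1] ** 2])


def _tensor_to_field(T: np.ndarray, surface, geometry) -> TangentField:
    """Leading eigenvector of per-vertex 2x2 tensors, magnitude lam1 - lam2."""
    xx, xy, yy = T[:, 0], T[:, 1], T[:, 2]
    disc = np.sqrt(np.maximum((xx - yy) ** 2 + 4 * xy**2, 0.0))
    mag = disc  # lam1 - lam2
    theta = 0.5 * np.arctan2(2 * xy, xx - yy)
    coeffs = np.column_stack([mag * np.cos(theta), mag * np.sin(theta)])
    coeffs[~np.isfinite(coeffs)] = 0.0
    return TangentField(coeffs, surface, geometry)


def fold_orientation(
    sulc,
    curv,
    surface: CorticalSurface,
    fwhm_mm: float = 10.0,
    geometry: str = "folded",
) -> TangentField:
    """Fold-orientation field from sulcal depth and curvature maps.

    The two gradient fields are combined by summing their axial second-moment
    tensors; the tensor components are smoothed with the given kernel, and
    the leading eigenvector gives the orientation with magnitude
    lambda_1 - lambda_2 (zero magnitude means undefined orientation).
    """
    gs = compute_gradient(sulc, surface, geometry)
    gc = compute_gradient(curv, surface, geometry)
    T = _axial_tensor(gs) + _axial_tensor(gc)
    if fwhm_mm > 0:
        T = smooth_map(T.T, surface, fwhm_mm).T
        T = np.where(np.isfinite(T), T, 0.0)
    return _tensor_to_field(T, surface, geometry)


def angle_between(a: TangentField, b: TangentField) -> AngleDistribution:
    """Per-vertex minimum axial angle between two fields, in [0, 90] degrees."""
    ang = angle_between_fields(a, b)
    valid = np.isfinite(ang)
    if a.surface is not None:
        valid &= a.surface.cortex_mask
    sk = skew(ang[valid], bias=False) if valid.sum() > 2 else np.nan
    return AngleDistribution(angles=ang, valid=valid, skewness=float(sk))


def alignment_skew_test(
    a: TangentField,
    b: TangentField,
    ensemble: SpinEnsemble,
    min_valid: int = 100,
):
    """Spin test for alignment between two orientation fields.

    Observed statistic: skewness of the axial angle distribution (positive
    when angles pile up near zero, i.e. aligned fields). Null: the first
    field is spun (orientations parallel-transported through the rotation)
    and the skewness recomputed. One-sided for positive skew.

    Returns ``(skewness, p_spin, low_power_flag)``.
    """
    obs = angle_between(a, b)
    if not np.isfinite(obs.skewness):
        raise ValueError("degenerate angle distribution (zero variance)")
    low_power = int(obs.valid.sum()) < min_valid
    null = np.empty(ensemble.n_spins)
    for s in range(ensemble.n_spins):
        aspun = spin_tangent_field(a, ensemble, s)
        null[s] = angle_between(aspun, b).skewness
    return obs.skewness, _pvalue(obs.skewness, null, "greater"), low_power


def _roi_mean_axis(field: TangentField, verts: np.ndarray):
    """Axial mean direction of a tangent field over a vertex set, as a 3-vector."""
    v3 = field.vectors3d()[verts]
    T = v3.T @ v3
    w, U = np.linalg.eigh(T)
    return U[:, -1], w[-1] - w[-2]


def roi_axis_alignment(
    parcellation: np.ndarray,
    field: TangentField,
    ensemble: SpinEnsemble,
    min_axis_ratio: float = 1.2,
):
    """Alignment between each ROI's short axis and the mean field direction.

    Per ROI: PCA of member-vertex 3-D coordinates yields the in-surface long
    and short axes (the smallest-variance component approximates the surface
    normal); the short axis is projected into the ROI's mean tangent plane
    and compared with the axial mean of the field over the ROI. The skewness
    of the per-ROI angles is tested by spinning the field. ROIs with in-plane
    axis ratio below ``min_axis_ratio`` are flagged near-degenerate and kept
    out of the skewness.

    Returns a dict with ``angles`` (per ROI), ``degenerate`` flags,
    ``skewness``, and ``p_spin``.
    """
    surface = field.surface
    rois = [int(p) for p in np.unique(parcellation[parcellation > 0])]

    def roi_angles(f: TangentField):
        angles, degenerate = {}, {}
        for pid in rois:
            verts = np.flatnonzero(parcellation == pid)
            coords = surface.vertices[verts]
            c = coords - coords.mean(0)
            w, U = np.linalg.eigh(c.T @ c)  # ascending
            normal = U[:, 0]
            long_axis, short_axis = U[:, 2], U[:, 1]
            ratio = np.sqrt(w[2] / w[1]) if w[1] > 0 else np.inf
            degenerate[pid] = ratio < min_axis_ratio
            mean_dir, strength = _roi_mean_axis(f, verts)
            if strength <= 0:
                angles[pid] = np.nan
                continue
            # project both axes into the ROI tangent plane (orthogonal to normal)
            sa = short_axis - (short_axis @ normal) * normal
            md = mean_dir - (mean_dir @ normal) * normal
            if np.linalg.norm(sa) == 0 or np.linalg.norm(md) == 0:
                angles[pid] = np.nan
                continue
            cosang = abs(sa @ md) / (np.linalg.norm(sa) * np.linalg.norm(md))
            angles[pid] = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
        return angles, degenerate

    angles, degenerate = roi_angles(field)
    usable = [
        pid for pid in rois if np.isfinite(angles[pid]) and not degenerate[pid]
    ]
    obs = skew([angles[p] for p in usable], bias=False) if len(usable) > 2 else np.nan
    null = np.empty(ensemble.n_spins)
    for s in range(ensemble.n_spins):
        fa, _ = roi_angles(spin_tangent_field(field, ensemble, s))
        vals = [fa[p] for p in usable if np.isfinite(fa[p])]
        null[s] = skew(vals, bias=False) if len(vals) > 2 else np.nan
    p = _pvalue(obs, null, "greater") if np.isfinite(obs) else np.nan
    return {
        "angles": angles,
        "degenerate": degenerate,
        "skewness": float(obs) if np.isfinite(obs) else np.nan,
        "p_spin": p,
    }
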