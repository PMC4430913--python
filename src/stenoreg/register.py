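"""Control-point registration of the two modalities and 3D stenosis recovery.

The tracked 3D artery is rotated to the angiogram's view and
orthographically projected to the (u, v) plane, keeping per-pixel
provenance to the contributing voxel.  Control points (start /
bifurcation / end landmarks) from both modalities are normalized —
centroid to the origin, RMS distance from the origin scaled to sqrt(2) —
an affine transform is fitted on the normalized pairs (exact for three
points, least squares for more), then de-normalized.  All point algebra
uses the row-vector convention ``[u v 1] · T``; ``T`` maps CTA-frame
coordinates to angiogram-frame coordinates, so warping the angiogram into
the CTA frame samples the angiogram at ``[p 1] · T`` (inverse warping) and
a stenosis pixel marked on the angiogram travels by ``T^{-1}``.

If the transformed stenosis point misses the CTA artery, it is localized
by arc length: the two nearest points where the registered centrelines
intersect bracket the stenosis; the angiogram-side arc lengths l1', l2' to
those points are rescaled onto the CTA-side centreline length L as
``l1 = l1' L / (l1' + l2')`` (so ``l1 + l2 = L`` identically) and the CTA
centreline is walked l1 from the first bracketing point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from . import skeletonops as sk
from .angio import ControlPoint
from .ctaseg import ArteryModel
from .geometry import ViewAngles, rotate_points, volume_center

__all__ = [
    "ProjectedArtery",
    "PointNormalization",
    "Affine2D",
    "CorrespondenceSet",
    "RegisteredPlane",
    "StenosisLocalization",
    "rotate_and_project",
    "normalize_points",
    "estimate_affine",
    "register_artery",
    "localize_stenosis",
    "stenosis_lengths",
    "back_project",
    "refine_tip_points",
]


@dataclass
class ProjectedArtery:
    """Binary projection I_C with control points P_C and voxel provenance."""

    image: np.ndarray  # bool, indexed [v, u]
    points: list  # [ControlPoint]
    back_map: dict  # (u, v) -> (x, y, z) voxel of the viewer-nearest contributor
    angles: ViewAngles
    volume_shape: tuple


def rotate_and_project(model: ArteryModel, angles: ViewAngles,
                       image_size=None) -> ProjectedArtery:
    """Rotate an artery about the volume centroid and project it to (u, v).

    ``(u, v) = (round(x'), round(y'))`` after rotation; among voxels
    mapping to one pixel the viewer-nearest (smallest depth z') wins the
    provenance entry.  Keypoints are projected identically, preserving
    roles and order.
    """
    vox = np.argwhere(model.M)  # (z, y, x)
    if len(vox) == 0:
        raise ValueError("cannot project an empty artery model")
    shape = model.M.shape
    center = volume_center(shape)
    pts = vox[:, ::-1].astype(float)  # (x, y, z)
    rot = rotate_points(pts, angles, center=center)
    uv = np.rint(rot[:, :2]).astype(int)
    depth = rot[:, 2]

    if image_size is None:
        image_size = (shape[1], shape[2])
    nrow, ncol = image_size
    ok = (uv[:, 0] >= 0) & (uv[:, 0] < ncol) & (uv[:, 1] >= 0) & (uv[:, 1] < nrow)
    uv, depth, vox = uv[ok], depth[ok], vox[ok]

    image = np.zeros((nrow, ncol), dtype=bool)
    image[uv[:, 1], uv[:, 0]] = True
    back_map = {}
    order = np.argsort(-depth)  # write far voxels first; nearest wins
    for i in order:
        u, v = int(uv[i, 0]), int(uv[i, 1])
        z, y, x = (int(c) for c in vox[i])
        back_map[(u, v)] = (x, y, z)

    points = []
    for kp in model.keypoints:
        p = rotate_points(
            np.array([[kp.col, kp.row, kp.z]], float), angles, center=center
        )[0]
        points.append(ControlPoint(u=int(round(p[0])), v=int(round(p[1])), role=kp.role))
    return ProjectedArtery(
        image=image, points=points, back_map=back_map, angles=angles,
        volume_shape=shape,
    )


def refine_tip_points(proj: ProjectedArtery) -> ProjectedArtery:
    """Move projected start/end landmarks onto the 2D vessel tips.

    Tracked keypoints are slice centroids; after projection they sit about
    one radius inside the 2D tube tip.  Thinning the projection and
    extending the nearest skeleton endpoint to the mask boundary gives the
    landmark the same "tube tip" semantics the angiogram side uses, so
    corresponding landmarks measure the same anatomical point.
    """
    skel = morphology.thin(proj.image)
    ends = np.argwhere(sk.end_points(skel))
    refined = []
    for p in proj.points:
        if p.role in ("start", "end") and len(ends) > 0:
            d2 = ((ends - [p.v, p.u]) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            if d2[j] <= 64:  # only adopt a nearby skeleton endpoint
                tip = sk.extend_to_boundary(proj.image, skel, tuple(ends[j]))
                refined.append(ControlPoint(u=int(tip[1]), v=int(tip[0]), role=p.role))
                continue
        refined.append(p)
    proj.points = refined
    return proj


# ---------------------------------------------------------------------------
# landmark normalization and affine estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointNormalization:
    """Centroid/scale pair with its 3x3 de-normalization matrix N.

    ``N`` maps a *normalized* row vector ``[u v 1]`` back to raw
    coordinates: ``[u v 1] · N = [u/S + u_bar, v/S + v_bar, 1]``.
    """

    centroid: tuple  # (u_bar, v_bar)
    scale: float  # S

    @property
    def matrix(self) -> np.ndarray:
        ub, vb = self.centroid
        s = self.scale
        return np.array([[1.0 / s, 0.0, 0.0], [0.0, 1.0 / s, 0.0], [ub, vb, 1.0]])


def normalize_points(pts):
    """Translate the centroid to the origin and scale RMS radius to sqrt(2).

    Returns ``(normalized_points, PointNormalization)``.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    n = len(pts)
    if n < 3:
        raise ValueError("at least 3 control points are required")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    ssq = float((centered**2).sum())
    if ssq == 0.0:
        raise ValueError("control points are all identical: scale undefined")
    scale = np.sqrt(2.0 * n) / np.sqrt(ssq)
    norm = PointNormalization(centroid=(centroid[0], centroid[1]), scale=scale)
    return centered * scale, norm


@dataclass(frozen=True)
class Affine2D:
    """2D affine transform acting on row vectors: ``[u v 1] · T``."""

    matrix: np.ndarray  # 3x3, last column (0, 0, 1)^T

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).copy()
        m[:, 2] = (0.0, 0.0, 1.0)
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValueError("singular affine transform")
        object.__setattr__(self, "matrix", m)

    def transform(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        return (h @ self.matrix)[:, :2]

    def inverse(self) -> "Affine2D":
        return Affine2D(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Ordered control-point pairs: source (P_C side) -> target (P_A side)."""

    source: np.ndarray  # (n, 2) (u, v)
    target: np.ndarray

    def __post_init__(self):
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        tgt = np.atleast_2d(np.asarray(self.target, dtype=float))
        if len(src) != len(tgt):
            raise ValueError("source and target must pair up")
        if len(src) < 3:
            raise ValueError("at least 3 correspondences are required")
        for name, side in (("source", src), ("target", tgt)):
            if len(np.unique(side, axis=0)) != len(side):
                raise ValueError(f"repeated points on the {name} side")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    def __len__(self):
        return len(self.source)


def estimate_affine(corr: CorrespondenceSet) -> Affine2D:
    """Fit the de-normalized affine transform from control-point pairs.

    Both sides are normalized, the reduced 3x2 transform is solved exactly
    for three pairs (least squares for more), embedded as a 3x3 affine,
    and de-normalized as ``T = N^{-1} · T_tilde · N'`` so that ``T`` maps
    raw source-frame (CTA) coordinates to raw target-frame (angiogram)
    coordinates.
    """
    src_n, norm_src = normalize_points(corr.source)
    tgt_n, norm_tgt = normalize_points(corr.target)
    a = np.hstack([src_n, np.ones((len(src_n), 1))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("collinear source control points: affine underdetermined")
    t_red, *_ = np.linalg.lstsq(a, tgt_n, rcond=None)
    t_tilde = np.column_stack([t_red, (0.0, 0.0, 1.0)])
    t = np.linalg.inv(norm_src.matrix) @ t_tilde @ norm_tgt.matrix
    return Affine2D(t)


# ---------------------------------------------------------------------------
# registration and stenosis localization
# ---------------------------------------------------------------------------


@dataclass
class RegisteredPlane:
    """Both arteries resampled onto one (u, v) plane (the CTA frame)."""

    angio: np.ndarray  # warped I_A'
    cta: np.ndarray  # I_C


def register_artery(i_a, proj: ProjectedArtery, t: Affine2D) -> RegisteredPlane:
    """Warp the angiogram artery mask into the CTA projection frame.

    Output pixel ``p`` (CTA frame) takes the angiogram value at
    ``[p 1] · T`` with nearest-neighbor sampling.
    """
    i_a = np.asarray(i_a, dtype=bool)
    nrow, ncol = proj.image.shape
    uu, vv = np.meshgrid(np.arange(ncol), np.arange(nrow))
    pts = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
    src = np.rint(t.transform(pts)).astype(int)
    su, sv = src[:, 0], src[:, 1]
    ok = (su >= 0) & (su < i_a.shape[1]) & (sv >= 0) & (sv < i_a.shape[0])
    warped = np.zeros(nrow * ncol, dtype=bool)
    warped[ok] = i_a[sv[ok], su[ok]]
    return RegisteredPlane(angio=warped.reshape(nrow, ncol), cta=proj.image.copy())


@dataclass
class StenosisLocalization:
    """The marked stenosis carried from the angiogram onto the CTA artery."""

    marked_uv: tuple  # angiogram frame
    transformed_uv: tuple  # CTA frame, float
    cta_pixel: tuple  # (u, v) on the CTA artery
    p_k: tuple | None = None
    p_l: tuple | None = None
    l1_prime: float | None = None
    l2_prime: float | None = None
    length_L: float | None = None
    l1: float | None = None
    l2: float | None = None
    voxel: tuple | None = None  # (x, y, z), set by back_project
    mm: tuple | None = None


def stenosis_lengths(l1_prime: float, l2_prime: float, length: float):
    """Rescale angiogram-side arc lengths onto the CTA centreline.

    ``l1 = l1' L / (l1' + l2')`` and ``l2 = l2' L / (l1' + l2')``, so
    ``l1 + l2 = L`` identically.
    """
    denom = l1_prime + l2_prime
    if denom <= 0:
        raise ValueError("arc lengths must be positive")
    return l1_prime * length / denom, l2_prime * length / denom


def _nearest_true(mask, point_vu):
    """Nearest True pixel of ``mask`` to a float (row, col) point."""
    pts = np.argwhere(mask)
    if len(pts) == 0:
        return None, np.inf
    d2 = ((pts - np.asarray(point_vu, float)) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    return tuple(int(c) for c in pts[i]), float(np.sqrt(d2[i]))


def localize_stenosis(i_r: RegisteredPlane, stenosis_uv, t: Affine2D,
                      tol_px: float = 2.0) -> StenosisLocalization:
    """Locate the marked angiogram stenosis on the CTA artery in I_R.

    The marked point travels into the CTA frame by ``T^{-1}``.  If it
    lands within ``tol_px`` of the CTA artery it is snapped to the nearest
    CTA pixel directly; otherwise both channels are thinned and the
    stenosis is transferred by the arc-length ratio between the two
    centreline intersection points that bracket it.
    """
    s_uv = np.asarray(stenosis_uv, dtype=float)
    t_uv = t.inverse().transform(s_uv[None, :])[0]
    t_vu = (t_uv[1], t_uv[0])

    near_angio, d_angio = _nearest_true(i_r.angio, t_vu)
    if near_angio is None or d_angio > max(tol_px, 3.0):
        raise ValueError("stenosis point lies off the registered angiogram artery")

    near_cta, d_cta = _nearest_true(i_r.cta, t_vu)
    loc = StenosisLocalization(
        marked_uv=(float(s_uv[0]), float(s_uv[1])),
        transformed_uv=(float(t_uv[0]), float(t_uv[1])),
        cta_pixel=(0, 0),
    )
    skel_c = morphology.thin(i_r.cta)
    if near_cta is not None and d_cta <= tol_px:
        # on-artery: snap onto the CTA centreline (the anatomical axis),
        # not the mask edge, so the depth recovered later is the lumen's
        near_axis, _ = _nearest_true(skel_c, t_vu)
        if near_axis is None:
            near_axis = near_cta
        loc.cta_pixel = (near_axis[1], near_axis[0])  # (u, v)
        return loc

    # arc-length fallback on the thinned plane I_R'
    skel_a = morphology.thin(i_r.angio)
    inter = skel_a & ndimage.binary_dilation(skel_c, morphology.disk(1))
    inter_pts = _intersection_points(inter)
    if len(inter_pts) < 2:
        raise ValueError(
            "fewer than two centreline intersection points; "
            "choose better control points"
        )

    s0, _ = _nearest_true(skel_a, t_vu)
    # parameterize the angiogram centreline from one of its extremities
    # (double-sweep: the farthest pixel from an arbitrary one is an end)
    pts_a = np.argwhere(skel_a)
    d0 = sk.geodesic_distances(skel_a, [s0])
    vals = d0[tuple(pts_a.T)]
    vals = np.where(np.isfinite(vals), vals, -1.0)
    start = tuple(int(c) for c in pts_a[int(np.argmax(vals))])
    param = sk.geodesic_distances(skel_a, [start])
    ts = param[s0]
    below = [p for p in inter_pts if param[p] <= ts]
    above = [p for p in inter_pts if param[p] > ts]
    if not below or not above:
        # stenosis outside the bracketed span: use the two nearest points
        inter_sorted = sorted(inter_pts, key=lambda p: abs(param[p] - ts))
        if len(inter_sorted) < 2:
            raise ValueError("cannot bracket the stenosis on the centreline")
        p_k, p_l = inter_sorted[0], inter_sorted[1]
    else:
        p_k = max(below, key=lambda p: param[p])
        p_l = min(above, key=lambda p: param[p])

    d_from_s0 = sk.geodesic_distances(skel_a, [s0])
    l1p, l2p = float(d_from_s0[p_k]), float(d_from_s0[p_l])
    if not (np.isfinite(l1p) and np.isfinite(l2p)):
        raise ValueError("intersection points unreachable along the centreline")

    q_k, _ = _nearest_true(skel_c, p_k)
    q_l, _ = _nearest_true(skel_c, p_l)
    d_c = sk.geodesic_distances(skel_c, [q_k])
    length_l = float(d_c[q_l])
    if not np.isfinite(length_l):
        raise ValueError("CTA centreline is disconnected between the brackets")
    l1, l2 = stenosis_lengths(l1p, l2p, length_l)
    path = sk.trace_path(d_c, q_l)  # q_k -> q_l
    px = sk.walk_length(path, l1)

    loc.p_k, loc.p_l = (p_k[1], p_k[0]), (p_l[1], p_l[0])
    loc.l1_prime, loc.l2_prime = l1p, l2p
    loc.length_L, loc.l1, loc.l2 = length_l, l1, l2
    loc.cta_pixel = (px[1], px[0])
    return loc


def _intersection_points(inter_mask):
    """One representative (row, col) pixel per intersection component."""
    lab = measure.label(inter_mask, connectivity=2)
    pts = []
    for i in range(1, lab.max() + 1):
        comp = np.argwhere(lab == i)
        c = comp.mean(axis=0)
        j = int(np.argmin(((comp - c) ** 2).sum(axis=1)))
        pts.append(tuple(int(v) for v in comp[j]))
    return pts


def back_project(loc: StenosisLocalization, proj: ProjectedArtery, spacing,
                 snap_radius: int = 3) -> StenosisLocalization:
    """Recover the 3D voxel behind the located CTA pixel.

    Uses the projection's provenance map; if the exact pixel has no
    provenance the nearest mapped pixel within ``snap_radius`` is used.
    Fills ``loc.voxel`` (x, y, z) and ``loc.mm`` (voxel * spacing).
    """
    u, v = loc.cta_pixel
    vox = proj.back_map.get((u, v))
    if vox is None:
        best, best_d = None, np.inf
        for (uu, vv), cand in proj.back_map.items():
            d = np.hypot(uu - u, vv - v)
            if d <= snap_radius and d < best_d:
                best, best_d = cand, d
        if best is None:
            raise ValueError(
                f"no provenance within {snap_radius} px of pixel ({u}, {v})"
            )
        vox = best
    dz, dy, dx = spacing
    x, y, z = vox
    loc.voxel = (x, y, z)
    loc.mm = (x * dx, y * dy, z * dz)
    return loc
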