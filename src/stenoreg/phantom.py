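"""Synthetic vascular phantoms for both imaging modalities.

Two generators are provided with exhaustive ground truth, so that every
downstream stage (2D segmentation, 3D tracking, registration, stenosis
localization) can be exercised without clinical data:

* :func:`make_angiogram_phantom` draws dark anti-aliasable tubes over a
  noisy bright background, emulating an X-ray angiogram frame.
* :func:`make_cta_phantom` builds a Hounsfield-unit volume containing
  air/lung regions, soft tissue, myocardium-range tissue, an aortic
  cylinder and bright contrast-filled artery tubes with branches and an
  optional stenotic narrowing, encoded back to raw integers through the
  DICOM rescale convention ``raw = (HU - intercept) / slope``.
* :func:`project_phantom` produces the angiogram that a given rotation +
  orthographic projection of the 3D truth would yield, recording the exact
  geometry so registration results can be scored against truth.

Tube membership is defined geometrically: a pixel/voxel belongs to a tube
iff its center lies within the local radius of the branch polyline
(Euclidean distance; radius linearly interpolated along each segment).
Noise is additive Gaussian, clipped to the valid intensity range.  With a
fixed seed every output is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ViewAngles, rotate_points, volume_center

__all__ = [
    "Branch2D",
    "PhantomSpec2D",
    "PhantomTruth2D",
    "Branch3D",
    "Ellipsoid",
    "Cylinder",
    "StenosisSpec",
    "PhantomSpec3D",
    "PhantomTruth3D",
    "CTAVolume",
    "ProjectionGeometry",
    "make_angiogram_phantom",
    "make_cta_phantom",
    "project_phantom",
]

# Default tissue HU values: air/lung in region 1 (<= -225), soft tissue in
# region 2, myocardium in region 3 (+31..+390), contrast/aorta in region 4
# (+391..+1000).
DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "lung": -850.0,
    "soft": 0.0,
    "myocardial": 150.0,
    "contrast": 450.0,
    "aorta": 500.0,
}


# ---------------------------------------------------------------------------
# 2D phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Branch2D:
    """A 2D vessel branch: polyline of (row, col) vertices and a width in px."""

    name: str
    points: np.ndarray  # (n, 2) float, (row, col)
    width: float

    def __post_init__(self):
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, float)))
        if self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError(f"branch {self.name!r}: need >= 2 (row, col) vertices")
        if self.width < 1:
            raise ValueError(f"branch {self.name!r}: width must be >= 1 px")


@dataclass(frozen=True)
class PhantomSpec2D:
    image_size: tuple = (128, 128)  # (rows, cols)
    tree: tuple = ()
    vessel_intensity: float = 60.0
    background_intensity: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.vessel_intensity >= self.background_intensity:
            raise ValueError("vessels must be darker than the background")
        object.__setattr__(self, "tree", tuple(self.tree))


@dataclass
class PhantomTruth2D:
    vessel_mask: np.ndarray
    centreline_mask: np.ndarray
    branch_points: list  # [(row, col), ...]
    end_points: list
    branch_labels: np.ndarray  # int image, 0 = background


def _segment_distance_field(shape, points, radii):
    """Signed membership of grid pixel centers against a tube polyline.

    Returns a boolean array: True where the pixel center is within the
    locally interpolated radius of the polyline.  Exact point-to-segment
    Euclidean distance, evaluated segment by segment on a bounding subgrid.
    """
    inside = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, float)
    radii = np.broadcast_to(np.asarray(radii, float), (len(pts),))
    ndim = pts.shape[1]
    for a, b, ra, rb in zip(pts[:-1], pts[1:], radii[:-1], radii[1:]):
        rmax = max(ra, rb)
        lo = np.maximum(np.floor(np.minimum(a, b) - rmax).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(a, b) + rmax).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        p = np.stack([g.astype(float) for g in grids], axis=-1)
        d = b - a
        dd = float(d @ d)
        if dd == 0:
            t = np.zeros(p.shape[:-1])
        else:
            t = np.clip(((p - a) @ d) / dd, 0.0, 1.0)
        nearest = a + t[..., None] * d
        dist = np.linalg.norm(p - nearest, axis=-1)
        r_loc = ra + t * (rb - ra)
        sel = dist <= r_loc
        idx = tuple(g[sel] for g in grids)
        inside[idx] = True
    return inside


def _polyline_stroke(shape, points):
    """8-connected 1-px stroke along a polyline (rounded vertices)."""
    from skimage.draw import line

    stroke = np.zeros(shape, dtype=bool)
    verts = np.rint(np.asarray(points, float)).astype(int)
    for a, b in zip(verts[:-1], verts[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        stroke[rr[ok], cc[ok]] = True
    return stroke


def make_angiogram_phantom(spec: PhantomSpec2D):
    """Render a synthetic angiogram frame and its ground truth.

    Returns ``(image, truth)`` where ``image`` is a float 2D array in
    [0, 255] (dark tubes on bright background) and ``truth`` a
    :class:`PhantomTruth2D`.
    """
    shape = tuple(spec.image_size)
    for br in spec.tree:
        if np.any(br.points < 0) or np.any(br.points >= np.array(shape, float)):
            raise ValueError(f"branch {br.name!r} polyline outside image")

    vessel_mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    centreline = np.zeros(shape, dtype=bool)
    for i, br in enumerate(spec.tree, start=1):
        m = _segment_distance_field(shape, br.points, br.width / 2.0)
        vessel_mask |= m
        labels[m & (labels == 0)] = i
        centreline |= _polyline_stroke(shape, br.points)
    centreline &= vessel_mask  # guarantee centreline ⊂ vessel_mask

    # key points: branch starts that attach to another branch are
    # bifurcation points; free first/last vertices are end points
    branch_points, end_points = [], []
    for i, br in enumerate(spec.tree):
        first = tuple(np.rint(br.points[0]).astype(int))
        last = tuple(np.rint(br.points[-1]).astype(int))
        on_other = any(
            _point_on_branch(br.points[0], other)
            for j, other in enumerate(spec.tree)
            if j != i
        )
        if on_other:
            branch_points.append(first)
        else:
            end_points.append(first)
        end_points.append(last)
    # keep listed points on the centreline stroke
    branch_points = [p for p in branch_points if centreline[p]]
    end_points = [p for p in end_points if centreline[p]]

    img = np.full(shape, float(spec.background_intensity))
    img[vessel_mask] = float(spec.vessel_intensity)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 255.0)
    truth = PhantomTruth2D(
        vessel_mask=vessel_mask,
        centreline_mask=centreline,
        branch_points=branch_points,
        end_points=end_points,
        branch_labels=labels,
    )
    return img, truth


def _point_on_branch(point, branch, tol=None) -> bool:
    """True if ``point`` lies within the tube of another branch."""
    pts = branch.points
    p = np.asarray(point, float)
    r = branch.width / 2.0 if tol is None else tol
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        dd = float(d @ d)
        t = 0.0 if dd == 0 else float(np.clip((p - a) @ d / dd, 0, 1))
        if np.linalg.norm(p - (a + t * d)) <= r + 1e-9:
            return True
    return False


# ---------------------------------------------------------------------------
# 3D phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Branch3D:
    """A 3D vessel branch: polyline of (z, y, x) vertices and radius profile.

    ``radius`` is a scalar or a per-vertex array (voxels), linearly
    interpolated along each segment.  ``parent`` names the branch this one
    stems from (None for a root); the first vertex of a child must lie
    inside its parent's tube.
    """

    label: str
    points: np.ndarray  # (n, 3) float, (z, y, x)
    radius: object = 2.0
    parent: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, float)))
        if self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError(f"branch {self.label!r}: need >= 2 (z, y, x) vertices")
        r = np.broadcast_to(np.asarray(self.radius, float), (len(self.points),)).copy()
        if np.any(r <= 0):
            raise ValueError(f"branch {self.label!r}: radii must be positive")
        object.__setattr__(self, "radius", r)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple  # (z, y, x)
    radii: tuple  # (rz, ry, rx)


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z) cylinder: aorta stand-in."""

    center_yx: tuple
    radius: float
    z_range: tuple  # (z0, z1) inclusive


@dataclass(frozen=True)
class StenosisSpec:
    """Focal narrowing: at fractional arclength ``position`` of ``label``,
    the tube radius dips linearly to ``narrowed_radius`` over ``extent``
    voxels of arclength each side."""

    label: str
    position: float  # 0..1 along the branch polyline
    narrowed_radius: float
    extent: float = 4.0


@dataclass(frozen=True)
class PhantomSpec3D:
    volume_size: tuple = (128, 128, 128)  # (nz, ny, nx)
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    artery_curves: tuple = ()  # Branch3D
    stenosis: StenosisSpec | None = None
    lungs: tuple = ()  # Ellipsoid
    myocardium: Ellipsoid | None = None
    aorta: Cylinder | None = None
    noise_sd: float = 0.0
    slope: float = 1.0
    intercept: float = -1024.0
    spacing: tuple = (0.75, 0.5, 0.5)  # (dz, dy, dx) mm
    seed: int = 0

    def __post_init__(self):
        hu = {**DEFAULT_TISSUE_HU, **self.tissue_hu}
        object.__setattr__(self, "tissue_hu", hu)
        object.__setattr__(self, "artery_curves", tuple(self.artery_curves))
        object.__setattr__(self, "lungs", tuple(self.lungs))
        if not (391.0 <= hu["contrast"] <= 1000.0):
            raise ValueError("contrast HU must lie in region 4 [+391, +1000]")
        if hu["lung"] > -225.0:
            raise ValueError("lung HU must lie in region 1 (<= -225)")
        if self.slope == 0:
            raise ValueError("rescale slope must be nonzero")
        if self.stenosis is not None:
            br = {b.label: b for b in self.artery_curves}.get(self.stenosis.label)
            if br is None:
                raise ValueError(f"stenosis label {self.stenosis.label!r} unknown")
            if self.stenosis.narrowed_radius >= float(np.min(br.radius)):
                raise ValueError("stenotic radius must be smaller than parent radius")


@dataclass
class PhantomTruth3D:
    label_masks: dict  # label -> 3D bool
    keypoints: dict  # label -> [(role, (z, y, x)), ...]
    stenosis_voxel: tuple | None
    view_to_image: "ProjectionGeometry | None" = None


@dataclass(frozen=True)
class CTAVolume:
    """Raw CTA voxels plus DICOM-style rescale metadata."""

    raw: np.ndarray  # (nz, ny, nx) int
    slope: float
    intercept: float
    spacing: tuple  # (dz, dy, dx) mm

    def __post_init__(self):
        if self.raw.ndim != 3 or self.raw.shape[0] < 3:
            raise ValueError("CTA volume needs >= 3 slices")
        if self.slope == 0:
            raise ValueError("rescale slope must be nonzero")


def _arclengths(points):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(points, radii, step=0.5):
    """Resample a polyline (and its radius profile) at uniform arclength."""
    s = _arclengths(points)
    total = s[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.stack([np.interp(si, s, points[:, k]) for k in range(points.shape[1])], axis=1)
    r = np.interp(si, s, radii)
    return out, r, si


def _apply_stenosis(points, radii, sten: StenosisSpec):
    """Dip the radius profile around the stenosis arclength position."""
    pts, r, s = _resample_polyline(points, radii, step=0.5)
    s0 = sten.position * s[-1]
    w = np.clip(1.0 - np.abs(s - s0) / sten.extent, 0.0, 1.0)
    r_new = r - w * (r - sten.narrowed_radius)
    center = pts[int(np.argmin(np.abs(s - s0)))]
    return pts, r_new, tuple(np.rint(center).astype(int))


def _ellipsoid_mask(shape, ell: Ellipsoid):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = ell.center
    rz, ry, rx = ell.radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_cta_phantom(spec: PhantomSpec3D):
    """Build a synthetic CTA volume and its ground truth.

    Returns ``(CTAVolume, PhantomTruth3D)``.  Raw values encode HU through
    the inverse rescale mapping ``raw = (HU - intercept) / slope``.
    """
    shape = tuple(spec.volume_size)
    hu_map = spec.tissue_hu
    hu = np.full(shape, float(hu_map["soft"]))

    for ell in spec.lungs:
        hu[_ellipsoid_mask(shape, ell)] = float(hu_map["lung"])
    if spec.myocardium is not None:
        hu[_ellipsoid_mask(shape, spec.myocardium)] = float(hu_map["myocardial"])
    if spec.aorta is not None:
        yy, xx = np.ogrid[: shape[1], : shape[2]]
        cy, cx = spec.aorta.center_yx
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.aorta.radius ** 2
        z0, z1 = spec.aorta.z_range
        hu[z0 : z1 + 1][:, disk] = float(hu_map["aorta"])

    by_label = {b.label: b for b in spec.artery_curves}
    label_masks = {}
    keypoints = {}
    stenosis_voxel = None
    occupied = np.zeros(shape, dtype=bool)
    for br in spec.artery_curves:
        pts, radii = br.points, br.radius
        if spec.stenosis is not None and spec.stenosis.label == br.label:
            pts, radii, stenosis_voxel = _apply_stenosis(pts, radii, spec.stenosis)
        mask = _segment_distance_field(shape, pts, radii)
        clash = mask & occupied
        # a child branch legitimately overlaps its parent near the takeoff
        if br.parent is not None and br.parent in label_masks:
            clash &= ~label_masks[br.parent]
        if np.any(clash) and br.parent is None:
            raise ValueError(
                f"artery branch {br.label!r} overlaps another label: ambiguous truth"
            )
        occupied |= mask
        label_masks[br.label] = mask
        kps = []
        first = tuple(np.rint(br.points[0]).astype(int))
        last = tuple(np.rint(br.points[-1]).astype(int))
        if br.parent is None:
            kps.append(("start", first))
        kps.append(("end", last))
        keypoints[br.label] = kps

    # children contribute bifurcation keypoints to their parent
    for br in spec.artery_curves:
        if br.parent is not None:
            if br.parent not in by_label:
                raise ValueError(f"unknown parent {br.parent!r} of {br.label!r}")
            bp = tuple(np.rint(br.points[0]).astype(int))
            keypoints[br.parent].append(("bifurcation", bp))

    for label, kps in keypoints.items():
        kps.sort(key=lambda item: ({"start": 0, "bifurcation": 1, "end": 2}[item[0]], item[1][0]))

    hu[occupied] = float(hu_map["contrast"])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape)
    hu = np.clip(hu, -1100.0, 1100.0)
    raw = np.rint((hu - spec.intercept) / spec.slope).astype(np.int16)
    vol = CTAVolume(raw=raw, slope=spec.slope, intercept=spec.intercept, spacing=spec.spacing)
    truth = PhantomTruth3D(
        label_masks=label_masks,
        keypoints=keypoints,
        stenosis_voxel=stenosis_voxel,
    )
    if spec.aorta is not None:
        am = np.zeros(shape, dtype=bool)
        yy, xx = np.ogrid[: shape[1], : shape[2]]
        cy, cx = spec.aorta.center_yx
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.aorta.radius ** 2
        z0, z1 = spec.aorta.z_range
        am[z0 : z1 + 1][:, disk] = True
        truth.label_masks["Aorta"] = am
    return vol, truth


# ---------------------------------------------------------------------------
# projection of the 3D truth into a paired synthetic angiogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectionGeometry:
    """The exact rotation + orthographic projection that produced an image."""

    angles: ViewAngles
    center_xyz: tuple
    image_size: tuple  # (rows, cols)

    def project(self, voxels_zyx) -> np.ndarray:
        """Map (n, 3) voxel indices (z, y, x) to float (u, v) pixel coords."""
        v = np.atleast_2d(np.asarray(voxels_zyx, float))
        pts = v[:, ::-1]  # (x, y, z)
        rot = rotate_points(pts, self.angles, center=self.center_xyz)
        return rot[:, :2]  # (u, v) = (x', y')


def project_phantom(
    truth: PhantomTruth3D,
    angles: ViewAngles,
    volume_shape,
    noise_sd: float = 0.0,
    labels=None,
    vessel_intensity: float = 60.0,
    background_intensity: float = 200.0,
    image_size=None,
    seed: int = 0,
):
    """Orthographically project 3D truth tubes into a synthetic angiogram.

    Returns ``(image, geometry)``; ``geometry`` is also stored on
    ``truth.view_to_image``.  Vessels are dark on a bright background, the
    convention of clinical angiograms.  Voxels whose projection falls
    outside the image are dropped.
    """
    center = volume_center(volume_shape)
    if image_size is None:
        image_size = (volume_shape[1], volume_shape[2])
    geom = ProjectionGeometry(
        angles=angles, center_xyz=tuple(center), image_size=tuple(image_size)
    )
    if labels is None:
        labels = [k for k in truth.label_masks if k != "Aorta"]
    img = np.full(tuple(image_size), float(background_intensity))
    for label in labels:
        vox = np.argwhere(truth.label_masks[label])
        if len(vox) == 0:
            continue
        uv = np.rint(geom.project(vox)).astype(int)
        ok = (
            (uv[:, 0] >= 0)
            & (uv[:, 0] < image_size[1])
            & (uv[:, 1] >= 0)
            & (uv[:, 1] < image_size[0])
        )
        img[uv[ok, 1], uv[ok, 0]] = float(vessel_intensity)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    truth.view_to_image = geom
    return img, geom
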