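"""Coronary artery segmentation, labeling and 3D reconstruction from CTA.

Pipeline: raw voxels are rescaled to Hounsfield units (HU), each slice is
classified into four anatomical HU regions, a lung mask removes pulmonary
tissue and vessels, the aorta is found by Hough circle detection in the
initial slices, vessels are enhanced with a multiscale Hessian (Frangi)
filter, and each coronary artery is reconstructed by *intersection
tracking*: starting from a seed component, the artery cross-section is
propagated slice by slice through region overlap.  At bifurcations all
branches are followed; the retained main artery is the branch chain that
reaches deepest (terminating side branches are removed, except long RCA
branches — R-PDA / R-PLB — which are preserved above a slice-length
threshold).  A short backtracking window bridges slices where the artery
momentarily vanishes.

HU region convention (half-open so the regions partition the range):
region 1: HU <= -225 (air, lung); region 2: -225 < HU <= +30 (soft
tissue); region 3: +30 < HU <= +390 (myocardium, uncontrasted arteries);
region 4: +390 < HU <= +1000 (contrast, aorta, bone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.transform import hough_circle, hough_circle_peaks

from . import skeletonops as sk
from .phantom import CTAVolume

__all__ = [
    "Seed",
    "Keypoint",
    "ArteryModel",
    "TrackConfig",
    "VesselnessSlice",
    "TrackingError",
    "to_hounsfield",
    "classify_regions",
    "build_lung_mask",
    "segment_aorta",
    "vesselness_score",
    "frangi_enhance",
    "binarize_slices",
    "detect_bifurcation",
    "track_artery",
    "derive_lad_lcx_seeds",
]


class TrackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class Seed:
    """Tracking seed: a voxel on a segmented component of its slice."""

    z: int
    row: int
    col: int
    label: str = "LM"  # LM | LAD | LCX | RCA


@dataclass(frozen=True)
class Keypoint:
    role: str  # start | bifurcation | end
    z: int
    row: int
    col: int


@dataclass
class ArteryModel:
    """Per-label 3D occupancy matrix M with its keypoint list M^p."""

    label: str
    M: np.ndarray  # (nz, ny, nx) bool
    keypoints: list = field(default_factory=list)

    @property
    def start(self):
        kps = [k for k in self.keypoints if k.role == "start"]
        return kps[0] if kps else None

    @property
    def end(self):
        kps = [k for k in self.keypoints if k.role == "end"]
        return kps[-1] if kps else None

    def bifurcations(self):
        return [k for k in self.keypoints if k.role == "bifurcation"]


@dataclass(frozen=True)
class TrackConfig:
    """Tunables of the intersection tracking stage.

    preserve_len
        Terminating side branches tracked for at least this many slices are
        kept (the RCA's R-PDA and R-PLB rule).
    dilate_px, lookahead
        Backtracking window: when the next slice has no overlapping
        component, the current region is dilated by ``dilate_px`` and up to
        ``lookahead`` subsequent slices are searched before the artery is
        declared ended.
    stop_at_first_bifurcation
        LM mode: the artery ends where it first bifurcates (LAD/LCX take
        over from there).
    """

    preserve_len: int = 15
    dilate_px: int = 3
    lookahead: int = 3
    stop_at_first_bifurcation: bool = False
    vessel_threshold: float = 0.15
    polarity: str = "paper"
    lad_side: str = "left"


@dataclass
class VesselnessSlice:
    v: np.ndarray  # in [0, 1]
    scale_of_max: np.ndarray


# ---------------------------------------------------------------------------
# HU conversion and region classification
# ---------------------------------------------------------------------------


def to_hounsfield(vol: CTAVolume) -> np.ndarray:
    """HU = raw * slope + intercept, clipped to [-1100, +1100]."""
    if vol.slope is None or vol.intercept is None:
        raise ValueError("missing rescale slope/intercept metadata")
    if vol.slope == 0:
        raise ValueError("rescale slope must be nonzero")
    hu = vol.raw.astype(float) * vol.slope + vol.intercept
    return np.clip(hu, -1100.0, 1100.0)


REGION_EDGES = (-225.0, 30.0, 390.0, 1000.0)


def classify_regions(hu) -> np.ndarray:
    """Classify HU voxels into anatomical regions 1-4 (0 = unclassified)."""
    hu = np.asarray(hu, dtype=float)
    region = np.zeros(hu.shape, dtype=np.int8)
    region[hu <= REGION_EDGES[0]] = 1
    region[(hu > REGION_EDGES[0]) & (hu <= REGION_EDGES[1])] = 2
    region[(hu > REGION_EDGES[1]) & (hu <= REGION_EDGES[2])] = 3
    region[(hu > REGION_EDGES[2]) & (hu <= REGION_EDGES[3])] = 4
    return region


def build_lung_mask(hu) -> np.ndarray:
    """Per-slice mask that removes lung and pulmonary vessels.

    Region-1 pixels are binarized per slice, holes (pulmonary vessels) are
    filled, and the complement is returned: True where tissue is kept.
    """
    region1 = classify_regions(hu) == 1
    keep = np.empty_like(region1)
    for z in range(region1.shape[0]):
        lung = ndimage.binary_fill_holes(region1[z])
        keep[z] = ~lung
    return keep


# ---------------------------------------------------------------------------
# aorta segmentation
# ---------------------------------------------------------------------------


def segment_aorta(hu, slices, radius_range, min_accum: float = 0.4) -> ArteryModel:
    """Detect the aorta as a circular region-4 object in the initial slices.

    Per slice: region-4 pixels are binarized, small objects removed, and a
    Hough circle transform over ``radius_range`` (pixels) finds the best
    circle; its disk (intersected with the filled region-4 mask) is
    accumulated into ``M_Aorta``.
    """
    hu = np.asarray(hu, dtype=float)
    rmin, rmax = int(radius_range[0]), int(radius_range[1])
    if rmin <= 0 or rmax < rmin:
        raise ValueError("radius_range must be positive and increasing")
    region4 = classify_regions(hu) == 4
    M = np.zeros(hu.shape, dtype=bool)
    radii = np.arange(rmin, rmax + 1)
    found_any = False
    for z in slices:
        if z < 0 or z >= hu.shape[0]:
            raise ValueError(f"slice {z} outside the volume")
        binary = morphology.remove_small_objects(region4[z], max_size=19)
        if not np.any(binary):
            continue
        filled = ndimage.binary_fill_holes(binary)
        edges = filled ^ ndimage.binary_erosion(filled)
        res = hough_circle(edges, radii)
        accums, cxs, cys, rads = hough_circle_peaks(res, radii, total_num_peaks=1)
        if len(accums) == 0 or accums[0] < min_accum:
            continue
        cy, cx, rad = float(cys[0]), float(cxs[0]), float(rads[0])
        yy, xx = np.ogrid[: hu.shape[1], : hu.shape[2]]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        M[z] = disk & filled
        found_any = True
    if not found_any:
        warnings.warn("no aortic circle found in the requested slices")
    return ArteryModel(label="Aorta", M=M)


# ---------------------------------------------------------------------------
# vessel enhancement
# ---------------------------------------------------------------------------


def _score_arrays(l1, l2, phi1, phi2, polarity):
    """Vectorized tube-likeness score from ordered Hessian eigenvalues."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (np.abs(l1) / np.abs(np.where(l2 != 0, l2, 1.0))) ** 2, 0.0)
    s2 = l1**2 + l2**2
    v = np.exp(-rb2 / (2.0 * phi1**2)) * (1.0 - np.exp(-s2 / (2.0 * phi2**2)))
    if polarity == "paper":
        v = np.where(l1 < 0, 0.0, v)
    elif polarity == "bright_vessels":
        v = np.where(l2 > 0, 0.0, v)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    v = np.where(l2 == 0, 0.0, v)
    return v


def vesselness_score(l1, l2, phi1: float = 0.75, phi2: float = 25.0,
                     polarity: str = "paper") -> float:
    """Tube-likeness in [0, 1] from ordered eigenvalues ``|l1| <= |l2|``.

    Returns 0 when the sign condition fires (``l1 < 0`` for the default
    polarity; ``l2 > 0`` for ``polarity="bright_vessels"``), otherwise
    ``exp(-R_B^2 / 2 phi1^2) * (1 - exp(-s^2 / 2 phi2^2))`` with
    ``R_B = |l1|/|l2|`` and ``s = sqrt(l1^2 + l2^2)``.
    """
    l1, l2 = float(l1), float(l2)
    if l2 == 0.0:
        if l1 != 0.0:
            raise ValueError("eigenvalue ordering violated: |l1| <= |l2| required")
        return 0.0
    if abs(l1) > abs(l2) + 1e-12:
        raise ValueError("eigenvalue ordering violated: |l1| <= |l2| required")
    return float(_score_arrays(np.float64(l1), np.float64(l2), phi1, phi2, polarity))


def hessian_eigenvalues(img, sigma: float):
    """Scale-normalized Hessian eigenvalues of a 2D image, ordered |l1|<=|l2|.

    Second derivatives are Gaussian derivatives at scale ``sigma``,
    multiplied by ``sigma**2`` (gamma-normalization).
    """
    img = np.asarray(img, dtype=float)
    ixx = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="nearest") * sigma**2
    iyy = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="nearest") * sigma**2
    ixy = ndimage.gaussian_filter(img, sigma, order=(1, 1), mode="nearest") * sigma**2
    half_trace = (ixx + iyy) / 2.0
    root = np.sqrt(((ixx - iyy) / 2.0) ** 2 + ixy**2)
    mu1 = half_trace + root
    mu2 = half_trace - root
    swap = np.abs(mu1) > np.abs(mu2)
    l1 = np.where(swap, mu2, mu1)
    l2 = np.where(swap, mu1, mu2)
    return l1, l2


def frangi_enhance(slice_img, scales=(1, 2, 3, 4), phi1: float = 0.75,
                   phi2: float = 25.0, polarity: str = "paper") -> VesselnessSlice:
    """Multiscale vesselness of a (lung-masked) slice: max over scales."""
    img = np.asarray(slice_img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("input slice contains non-finite values")
    best = np.zeros(img.shape)
    best_scale = np.zeros(img.shape)
    for sigma in scales:
        l1, l2 = hessian_eigenvalues(img, sigma)
        v = _score_arrays(l1, l2, phi1, phi2, polarity)
        better = v > best
        best = np.where(better, v, best)
        best_scale = np.where(better, sigma, best_scale)
    return VesselnessSlice(v=best, scale_of_max=best_scale)


def binarize_slices(hu, lung_keep=None, method: str = "vesselness",
                    cfg: TrackConfig = TrackConfig(), phi1: float = 0.75,
                    phi2: float = 25.0, scales=(1, 2, 3, 4)) -> np.ndarray:
    """Per-slice binary vessel candidates for the tracking stage.

    ``method="vesselness"`` thresholds the Frangi response at
    ``cfg.vessel_threshold``; ``method="region4"`` takes the contrast HU
    region directly.  Either way the lung mask (if given) is applied first.
    """
    hu = np.asarray(hu, dtype=float)
    out = np.zeros(hu.shape, dtype=bool)
    if method == "region4":
        out = classify_regions(hu) == 4
        if lung_keep is not None:
            out &= lung_keep
        return out
    if method != "vesselness":
        raise ValueError(f"unknown binarization method {method!r}")
    for z in range(hu.shape[0]):
        sl = hu[z].copy()
        if lung_keep is not None:
            sl[~lung_keep[z]] = sl.min()
        vs = frangi_enhance(sl, scales=scales, phi1=phi1, phi2=phi2,
                            polarity=cfg.polarity)
        out[z] = vs.v > cfg.vessel_threshold
    return out


# ---------------------------------------------------------------------------
# bifurcation detection
# ---------------------------------------------------------------------------


def detect_bifurcation(H):
    """Does this single 8-connected region contain a bifurcation?

    The region is thinned; a skeleton pixel with >= 3 neighbors marks a
    bifurcation.  If one is present the region is split at the branch
    locus (pixels closer to a branch point than to the background are
    cleared) and the resulting sub-regions are returned, largest first —
    the largest is conventionally the proximal trunk, the rest the distal
    branch regions.

    Returns ``(flag, branch_regions)`` where ``branch_regions`` excludes
    the proximal trunk.
    """
    H = np.asarray(H, dtype=bool)
    if not np.any(H):
        raise ValueError("empty region")
    if measure.label(H, connectivity=2).max() != 1:
        raise ValueError("region must be a single 8-connected component")
    skel = morphology.thin(H)
    branch = sk.branch_points(skel)
    if not np.any(branch):
        return False, []
    # cut a disk of the junction's local radius around every branch point
    dist_bg = ndimage.distance_transform_edt(H)
    split = H.copy()
    yy, xx = np.ogrid[: H.shape[0], : H.shape[1]]
    for r, c in np.argwhere(branch):
        radius = dist_bg[r, c] + 1.0
        split &= (yy - r) ** 2 + (xx - c) ** 2 > radius**2
    lab = measure.label(split, connectivity=2)
    regions = [lab == i for i in range(1, lab.max() + 1)]
    regions.sort(key=lambda m: int(np.count_nonzero(m)), reverse=True)
    return True, regions[1:]


# ---------------------------------------------------------------------------
# intersection tracking
# ---------------------------------------------------------------------------


def _centroid(region):
    pts = np.argwhere(region)
    return pts.mean(axis=0)


class _BranchNode:
    """One tracked branch chain between bifurcations (or to termination)."""

    __slots__ = ("slices", "children", "gap_slices")

    def __init__(self):
        self.slices = []  # [(z, 2D bool region)]
        self.children = []  # [_BranchNode]
        self.gap_slices = []

    @property
    def first_z(self):
        return self.slices[0][0]

    @property
    def last_z(self):
        return self.slices[-1][0]

    def subtree_depth(self):
        """Deepest slice index reached anywhere in the subtree."""
        d = self.last_z
        for ch in self.children:
            d = max(d, ch.subtree_depth())
        return d

    def subtree_length(self):
        """Total number of slices tracked in the subtree."""
        return len(self.slices) + sum(ch.subtree_length() for ch in self.children)


def _overlapping_components(lab, H):
    ids = np.unique(lab[H])
    return [int(i) for i in ids if i != 0]


def _track_tree(slices_lab, z0, comp_id, cfg, visited, stop_event):
    """Recursively follow a component chain; returns a _BranchNode."""
    nz = len(slices_lab)
    node = _BranchNode()
    z, cid = z0, comp_id
    while True:
        key = (z, cid)
        if key in visited:
            raise TrackingError(f"cyclic intersection: component revisited at slice {z}")
        visited.add(key)
        H = slices_lab[z] == cid
        node.slices.append((z, H))
        if stop_event.get("stop"):
            return node
        # advance to the next slice, with a backtracking window on failure
        nxt = None
        if z + 1 < nz:
            comps = _overlapping_components(slices_lab[z + 1], H)
            if comps:
                nxt = (z + 1, comps)
            else:
                Hd = ndimage.binary_dilation(H, morphology.disk(cfg.dilate_px))
                for zz in range(z + 1, min(z + 1 + cfg.lookahead, nz)):
                    comps = _overlapping_components(slices_lab[zz], Hd)
                    if comps:
                        node.gap_slices.extend(range(z + 1, zz))
                        nxt = (zz, comps)
                        break
        if nxt is None:
            return node  # artery ends here
        z_next, comps = nxt
        if len(comps) == 1:
            z, cid = z_next, comps[0]
            continue
        # bifurcation: spawn a child tracker per overlapping component
        if cfg.stop_at_first_bifurcation:
            stop_event["stop"] = True
            return node
        for c in comps:
            node.children.append(
                _track_tree(slices_lab, z_next, c, cfg, visited, stop_event)
            )
        return node


def _main_path(node):
    """Greedy deepest-descent: the longest root-to-leaf branch chain."""
    path = [node]
    cur = node
    while cur.children:
        cur = max(
            cur.children,
            key=lambda ch: (
                ch.subtree_depth(),
                np.count_nonzero(ch.slices[0][1]),
                -_centroid(ch.slices[0][1])[1],
            ),
        )
        path.append(cur)
    return path


def track_artery(binarized_slices, seed: Seed, cfg: TrackConfig = TrackConfig()) -> ArteryModel:
    """Reconstruct one coronary artery by slice-to-slice region overlap.

    Starting from the seed's component, the cross-section is propagated
    top to bottom.  At a bifurcation every branch is followed; the longest
    chain (deepest termination) is kept as the main artery, terminating
    side branches are removed unless tracked for at least
    ``cfg.preserve_len`` slices (R-PDA / R-PLB preservation).  One-slice
    dropouts are bridged by the backtracking window.

    Keypoints recorded in ``M^p``: the start centroid at the seed slice,
    the parent-region centroid at every bifurcation retained on the main
    path, and the end centroid at the final slice.
    """
    stack = np.asarray(binarized_slices, dtype=bool)
    if seed.z < 0 or seed.z >= stack.shape[0]:
        raise ValueError("seed slice outside the stack")
    if not stack[seed.z, seed.row, seed.col]:
        raise ValueError(
            f"seed ({seed.z}, {seed.row}, {seed.col}) does not lie on a "
            "segmented component of its slice"
        )
    slices_lab = [measure.label(stack[z], connectivity=2) for z in range(stack.shape[0])]
    seed_cid = int(slices_lab[seed.z][seed.row, seed.col])
    visited = set()
    stop_event = {"stop": False}
    root = _track_tree(slices_lab, seed.z, seed_cid, cfg, visited, stop_event)

    path = _main_path(root)
    M = np.zeros(stack.shape, dtype=bool)
    keypoints = []
    # start
    z0, H0 = path[0].slices[0]
    c0 = _centroid(H0)
    keypoints.append(Keypoint("start", z0, int(round(c0[0])), int(round(c0[1]))))
    for i, nd in enumerate(path):
        for z, H in nd.slices:
            M[z] |= H
        if nd.children:  # a bifurcation was taken at the end of this chain
            zb, Hb = nd.slices[-1]
            cb = _centroid(Hb)
            keypoints.append(
                Keypoint("bifurcation", zb, int(round(cb[0])), int(round(cb[1])))
            )
            # preserve long terminating branches that were not taken
            taken = path[i + 1] if i + 1 < len(path) else None
            for ch in nd.children:
                if ch is taken:
                    continue
                if cfg.preserve_len and ch.subtree_length() >= cfg.preserve_len:
                    _merge_subtree(M, ch)
                    zp, Hp = ch.slices[-1]
                    cp = _centroid(Hp)
                    keypoints.append(
                        Keypoint("end", zp, int(round(cp[0])), int(round(cp[1])))
                    )
    zE, HE = path[-1].slices[-1]
    cE = _centroid(HE)
    keypoints.append(Keypoint("end", zE, int(round(cE[0])), int(round(cE[1]))))
    return ArteryModel(label=seed.label, M=M, keypoints=keypoints)


def _merge_subtree(M, node):
    for z, H in node.slices:
        M[z] |= H
    for ch in node.children:
        _merge_subtree(M, ch)


def derive_lad_lcx_seeds(lm: ArteryModel, binarized_slices,
                         cfg: TrackConfig = TrackConfig()):
    """Seeds for LAD and LCX from the LM's terminal bifurcation.

    At the slice following the LM's last tracked cross-section, the two
    components overlapping it become the LAD and LCX starting regions;
    their centroids are the seeds.  Which is which follows ``cfg.lad_side``
    (default: the leftmost-in-image component is the LAD).
    """
    stack = np.asarray(binarized_slices, dtype=bool)
    zs = np.flatnonzero(M_any := lm.M.any(axis=(1, 2)))
    if len(zs) == 0:
        raise ValueError("LM model is empty")
    zb = int(zs[-1])
    if zb + 1 >= stack.shape[0]:
        raise ValueError("LM reaches the bottom of the stack without bifurcating")
    H = lm.M[zb]
    lab = measure.label(stack[zb + 1], connectivity=2)
    comps = _overlapping_components(lab, H)
    if len(comps) < 2:
        raise ValueError("LM has no bifurcation: cannot derive LAD/LCX seeds")
    if len(comps) > 2:
        cents = [tuple(np.round(_centroid(lab == c), 1)) for c in comps]
        raise ValueError(
            f"ambiguous {len(comps)}-way split below the LM; candidate region "
            f"centroids at slice {zb + 1}: {cents}"
        )
    seeds = []
    for c in comps:
        region = lab == c
        cy, cx = _centroid(region)
        r, col = int(round(cy)), int(round(cx))
        if not region[r, col]:  # snap to the nearest pixel of the region
            pts = np.argwhere(region)
            r, col = pts[np.argmin(((pts - [cy, cx]) ** 2).sum(axis=1))]
        seeds.append(Seed(z=zb + 1, row=int(r), col=int(col)))
    seeds.sort(key=lambda s: s.col)
    if cfg.lad_side == "left":
        lad, lcx = seeds[0], seeds[1]
    else:
        lcx, lad = seeds[0], seeds[1]
    lad = Seed(z=lad.z, row=lad.row, col=lad.col, label="LAD")
    lcx = Seed(z=lcx.z, row=lcx.row, col=lcx.col, label="LCX")
    return lad, lcx
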