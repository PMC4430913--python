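"""Main coronary artery segmentation and labeling in 2D X-ray angiograms.

The stage chain is: Haar-wavelet denoising -> starlet (isotropic
undecimated, "a trous") sharpening -> inversion and starlet detail-sum
segmentation -> morphological thinning and branch/end point detection ->
centreline detachment and labeling -> per-artery mask reconstruction with
candidate control points.

The starlet transform decomposes an image into detail planes
``w_j = c_{j-1} - c_j`` obtained by repeatedly smoothing with a separable
filter whose taps are dilated by ``2**(j-1)`` at level ``j`` (the "a trous"
scheme), so the reconstruction identity ``c_0 = c_L + sum_j w_j`` holds
exactly.  Angiogram vessels are darker than their background, so the image
is inverted before segmentation; the detail sum over levels {2,3,4,5} with
the spline-like filter [1,3,3,1]/8 responds strongly on vessel-scale
structures and is thresholded at ``k * sigma`` where ``sigma`` is a robust
(MAD-based) scale estimate of the detail sum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import ndimage
from skimage import measure, morphology

from . import skeletonops as sk

__all__ = [
    "STARLET_FILTER",
    "WaveletDecomposition",
    "CenterlineSet",
    "ControlPoint",
    "denoise_dwt",
    "swt_decompose",
    "sharpen_arteries",
    "segment_main_arteries",
    "extract_centerlines",
    "detach_and_label",
    "label_artery",
]

#: Separable smoothing filter used for sharpening and segmentation.
STARLET_FILTER = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0

SHARPEN_LEVELS = (1, 2, 3, 4, 5)
SEGMENT_LEVELS = (2, 3, 4, 5)


@dataclass
class WaveletDecomposition:
    """Starlet decomposition: scale planes c_0..c_L and details w_1..w_L."""

    scale_planes: list
    detail_planes: list
    filter_taps: np.ndarray
    levels_used: tuple

    def detail_sum(self, levels=None) -> np.ndarray:
        levels = self.levels_used if levels is None else levels
        out = np.zeros_like(self.scale_planes[0])
        for j in levels:
            out += self.detail_planes[j - 1]
        return out


@dataclass
class ControlPoint:
    """Candidate control point: (u, v) = (col, row) plus a landmark role."""

    u: int
    v: int
    role: str  # start | bifurcation | end


@dataclass
class CenterlineSet:
    """Skeleton, neighbor counts, keypoints and labels of a vessel mask."""

    mask: np.ndarray  # source segmentation
    skeleton: np.ndarray
    neighbor_counts: np.ndarray
    end_mask: np.ndarray
    branch_mask: np.ndarray
    labels: np.ndarray | None = None  # int image, 0 = background
    selected: np.ndarray | None = None

    @property
    def keypoints(self) -> np.ndarray:
        return self.end_mask | self.branch_mask


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------


def denoise_dwt(img, wavelet: str = "haar", level: int = 3, threshold=None):
    """Wavelet shrinkage denoising (hard universal threshold).

    A 3-level Haar decomposition is taken; every detail coefficient whose
    magnitude falls below the universal threshold
    ``sigma * sqrt(2 ln n)`` (``sigma`` estimated as MAD/0.6745 of the
    finest diagonal subband) is zeroed; the inverse transform is returned.
    An explicit ``threshold`` overrides the estimate.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("image must be 2D with both dimensions >= 8")
    coeffs = pywt.wavedec2(img, wavelet, level=level)
    if threshold is None:
        finest_diag = coeffs[-1][2]
        sigma = np.median(np.abs(finest_diag)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(img.size))
    else:
        thr = float(threshold)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        out.append(tuple(np.where(np.abs(d) > thr, d, 0.0) for d in detail))
    rec = pywt.waverec2(out, wavelet)
    return rec[: img.shape[0], : img.shape[1]]


# ---------------------------------------------------------------------------
# starlet (a trous) transform
# ---------------------------------------------------------------------------


def _filter_offsets(taps) -> np.ndarray:
    # even-length filters are anchored at offsets {-2,-1,0,+1} (len 4);
    # odd-length filters are centered
    n = len(taps)
    return np.arange(n) - n // 2


def _smooth_separable(img, taps, dilation: int) -> np.ndarray:
    """Separable smoothing with taps dilated by ``dilation`` (mirror pad)."""
    taps = np.asarray(taps, dtype=float)
    offsets = _filter_offsets(taps) * dilation
    pad = int(np.max(np.abs(offsets)))
    out = img
    for axis in (0, 1):
        padded = np.pad(
            out,
            [(pad, pad) if ax == axis else (0, 0) for ax in (0, 1)],
            mode="symmetric",
        )
        acc = np.zeros_like(out)
        n = out.shape[axis]
        for t, off in zip(taps, offsets):
            start = pad + off
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + n)
            acc += t * padded[tuple(sl)]
        out = acc
    return out


def swt_decompose(img, filter_taps=STARLET_FILTER, levels: int = 5) -> WaveletDecomposition:
    """Starlet decomposition of an image into ``levels`` detail planes.

    At level ``j`` the filter taps are dilated by ``2**(j-1)``;
    ``w_j = c_{j-1} - c_j``.  The filter must be normalized (taps sum to 1).
    """
    img = np.asarray(img, dtype=float)
    taps = np.asarray(filter_taps, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if not np.isclose(taps.sum(), 1.0, atol=1e-12):
        raise ValueError("filter taps must sum to 1")
    scales = [img]
    details = []
    c = img
    for j in range(1, levels + 1):
        c_next = _smooth_separable(c, taps, dilation=2 ** (j - 1))
        details.append(c - c_next)
        scales.append(c_next)
        c = c_next
    return WaveletDecomposition(
        scale_planes=scales,
        detail_planes=details,
        filter_taps=taps,
        levels_used=tuple(range(1, levels + 1)),
    )


def sharpen_arteries(img, filter_taps=STARLET_FILTER, levels=SHARPEN_LEVELS):
    """Starlet detail sum over levels {1..5}: vessel-sharpened image."""
    dec = swt_decompose(img, filter_taps, levels=max(levels))
    return dec.detail_sum(levels)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_main_arteries(
    img,
    filter_taps=STARLET_FILTER,
    levels=SEGMENT_LEVELS,
    k: float = 2.0,
    min_length: int = 30,
) -> np.ndarray:
    """Segment main arteries from a (denoised) angiogram.

    The image is inverted (vessels must be brighter than background for the
    detail planes to respond positively), the starlet detail sum over
    ``levels`` is thresholded at ``k * sigma`` (``sigma`` = MAD/0.6745 of
    the detail sum), components whose skeleton is shorter than
    ``min_length`` pixels are dropped, and holes are filled.
    """
    img = np.asarray(img, dtype=float)
    inverted = img.max() - img
    dec = swt_decompose(inverted, filter_taps, levels=max(levels))
    detail = dec.detail_sum(levels)
    med = np.median(detail)
    sigma = np.median(np.abs(detail - med)) / 0.6745
    mask = detail > k * sigma
    mask = _length_refinement(mask, min_length)
    return ndimage.binary_fill_holes(mask)


def _length_refinement(mask, min_length: int) -> np.ndarray:
    """Drop components whose thinned skeleton has < ``min_length`` pixels."""
    if not np.any(mask):
        return mask
    lab = measure.label(mask, connectivity=2)
    skel = morphology.thin(mask)
    keep = np.zeros(lab.max() + 1, dtype=bool)
    counts = np.bincount((lab * skel).ravel(), minlength=lab.max() + 1)
    keep[1:] = counts[1:] >= min_length
    return keep[lab]


# ---------------------------------------------------------------------------
# centrelines
# ---------------------------------------------------------------------------


def extract_centerlines(mask) -> CenterlineSet:
    """Thin a vessel mask and detect its end and branch pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("cannot extract centrelines from an empty mask")
    skeleton = morphology.thin(mask)
    counts = sk.neighbor_counts(skeleton)
    return CenterlineSet(
        mask=mask,
        skeleton=skeleton,
        neighbor_counts=counts,
        end_mask=counts == 2,
        branch_mask=sk.branch_points(skeleton),
    )


def detach_and_label(cs: CenterlineSet, min_len: int = 10) -> CenterlineSet:
    """Detach centrelines at branch points and label the remaining segments.

    Branch pixels are removed; additionally, skeleton pixels closer
    (Euclidean) to a branch point than to the nearest non-vessel pixel are
    cleared, which opens a radius-sized gap around every bifurcation.
    8-connected components shorter than ``min_len`` pixels are dropped; the
    rest are labeled 1..K.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    detached = cs.skeleton & ~cs.branch_mask
    if np.any(cs.branch_mask):
        # pixels no farther from a branch point than from the background
        # (i.e. within the local vessel radius of a junction) are cleared;
        # ties count as cleared so 1-px skeletons actually detach
        dist_branch = ndimage.distance_transform_edt(~cs.branch_mask)
        dist_bg = ndimage.distance_transform_edt(cs.mask)
        detached &= ~(dist_branch <= dist_bg)
    lab = measure.label(detached, connectivity=2)
    counts = np.bincount(lab.ravel(), minlength=lab.max() + 1)
    relabel = np.zeros(lab.max() + 1, dtype=np.int32)
    nxt = 1
    for i in range(1, lab.max() + 1):
        if counts[i] >= min_len:
            relabel[i] = nxt
            nxt += 1
    return replace(cs, labels=relabel[lab])


def label_artery(selected_labels, cs: CenterlineSet, seg, extend_tips: bool = False):
    """Reconstruct the selected artery and collect its control points.

    The selected centreline labels are inflated by the mask radius ``r``
    (the maximum distance-to-background over the selected centreline
    pixels) and intersected with the segmentation.  Candidate control
    points are the keypoints falling inside the reconstructed artery,
    ordered along the centreline from the start (the endpoint with the
    larger local vessel radius, i.e. the ostium side) to the end.

    With ``extend_tips`` the start/end landmarks are pushed outward along
    the local tangent to the mask boundary, compensating the tip erosion
    of thinning (useful when the landmarks feed a registration); without
    it every control point lies on the skeleton.

    Returns ``(artery_mask, [ControlPoint, ...])``.
    """
    seg = np.asarray(seg, dtype=bool)
    if cs.labels is None:
        raise ValueError("centrelines are not labeled; run detach_and_label first")
    selected = set(int(s) for s in selected_labels)
    if not selected:
        raise ValueError("no labels selected")
    present = set(np.unique(cs.labels)) - {0}
    unknown = selected - present
    if unknown:
        raise ValueError(f"unknown centreline label(s): {sorted(unknown)}")
    sel_mask = np.isin(cs.labels, sorted(selected))

    dist_bg = ndimage.distance_transform_edt(seg)
    r = float(dist_bg[sel_mask].max())
    dist_to_sel = ndimage.distance_transform_edt(~sel_mask)
    artery = (dist_to_sel <= r) & seg

    # keypoints inside the reconstructed artery
    kp_mask = cs.keypoints & artery
    if not np.any(kp_mask):
        raise ValueError(
            "no control points fall inside the selected artery; "
            "re-select centreline labels"
        )

    # order along the artery skeleton from the start (largest radius endpoint)
    skel = cs.skeleton & artery
    ends = [tuple(p) for p in np.argwhere(cs.end_mask & artery)]
    if ends:
        start_px = max(ends, key=lambda p: dist_bg[p])
    else:  # fall back to any keypoint
        start_px = tuple(np.argwhere(kp_mask)[0])
    dist = sk.geodesic_distances(skel, [start_px])

    points = []
    for r_, c_ in np.argwhere(kp_mask):
        if cs.branch_mask[r_, c_]:
            role = "bifurcation"
        elif (r_, c_) == start_px:
            role = "start"
        else:
            role = "end"
        d = dist[r_, c_]
        px = (int(r_), int(c_))
        if extend_tips and role in ("start", "end"):
            # thinning erodes tube tips by about one radius; push the
            # landmark back out to the mask boundary along the tangent
            px = sk.extend_to_boundary(artery, skel, px)
        points.append((d if np.isfinite(d) else np.inf,
                       ControlPoint(u=px[1], v=px[0], role=role)))
    points.sort(key=lambda t: t[0])
    return artery, [p for _, p in points]
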