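"""End-to-end orchestration on synthetic phantom pairs.

The phantom workflow mirrors the clinical one: a CTA volume with a known
coronary tree (and a stenotic narrowing) is generated; the paired
angiogram is the orthographic projection of that tree under known view
angles, optionally displaced by a mild in-plane affine (the residual
mismatch a specialist's manual view matching would leave) and noise.  The
2D branch segments the angiogram; the 3D branch tracks the artery through
the HU volume; registration fits the control-point affine and carries the
marked stenosis pixel back to a 3D voxel, which is scored against the
ground-truth stenosis voxel.

Specialist decisions that the clinical workflow takes interactively
(frame choice, artery selection, correspondence marking, the stenosis
mark) are emulated from the phantom ground truth and are all overridable
through the config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import angio, ctaseg, evalmetrics, phantom, register
from .geometry import ViewAngles

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "default_phantom_spec",
    "make_phantom_pair",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the phantom end-to-end run.

    ``jitter_px`` adds seeded Gaussian jitter to every control point on
    both sides before the affine fit, emulating imprecise landmark
    marking.  ``inplane`` is the (rotation deg, scale, du, dv) applied to
    the projected geometry when rendering the angiogram, so the affine fit
    has a nontrivial transform to recover.
    """

    seed: int = 0
    # an oblique lateral projection: angiograms image the coronary roughly
    # side-on (the beam near-perpendicular to the vessel course), so the
    # default view rotates the z-running artery into the image plane
    view: tuple = (-80.0, 10.0, 5.0)  # (theta_x, theta_y, theta_z) degrees
    inplane: tuple = (5.0, 1.05, 3.0, -2.0)  # rotation deg, scale, du, dv
    angio_noise_sd: float = 0.0
    cta_noise_sd: float = 0.0
    jitter_px: float = 0.0
    binarize: str = "region4"  # tracking input: region4 | vesselness
    tol_px: float = 2.0
    snap_radius: int = 3
    track: ctaseg.TrackConfig = field(
        # preserve the short diagonal branch so its endpoint serves as a
        # fourth registration landmark
        default_factory=lambda: ctaseg.TrackConfig(preserve_len=6)
    )
    min_length: int = 15
    min_len: int = 5
    detail_k: float = 2.0


@dataclass
class PipelineReport:
    config: dict
    transform: list  # row-major 9 numbers
    residuals_px: list
    stenosis_voxel: tuple
    stenosis_mm: tuple
    truth_voxel: tuple | None
    truth_distance_voxels: float | None
    angio_dice: float | None
    tracking_recall: float | None
    n_control_points: int


def default_phantom_spec(seed: int = 0) -> phantom.PhantomSpec3D:
    """The reference synthetic coronary geometry used by the test harness.

    A 128^3 volume holding two lung ellipsoids, a myocardial ellipsoid, a
    short aortic cylinder in the top slices, a gently curved main artery
    (radius 3 voxels, ~90 slices long) with a terminating diagonal side
    branch, and a focal stenosis at 60% of the main artery's arc length.
    """
    t = np.linspace(0.0, 1.0, 25)
    main_pts = np.column_stack(
        [
            18.0 + 92.0 * t,  # z
            42.0 + 28.0 * np.sin(np.pi * t * 0.9),  # y
            38.0 + 52.0 * t,  # x
        ]
    )
    # branch takes off from the main curve at t ~ 0.3 and drifts away
    tb = np.linspace(0.3, 0.42, 6)
    base = np.column_stack(
        [18.0 + 92.0 * tb, 42.0 + 28.0 * np.sin(np.pi * tb * 0.9), 38.0 + 52.0 * tb]
    )
    drift = np.column_stack(
        [np.zeros_like(tb), -np.linspace(0, 14, len(tb)), np.linspace(0, 10, len(tb))]
    )
    branch_pts = base + drift
    return phantom.PhantomSpec3D(
        volume_size=(128, 128, 128),
        artery_curves=(
            # proximal-to-distal taper, as in real coronaries (and what the
            # 2D start/end role assignment relies on)
            phantom.Branch3D(label="LAD", points=main_pts,
                             radius=np.linspace(3.6, 2.2, len(main_pts))),
            phantom.Branch3D(label="D1", points=branch_pts,
                             radius=np.linspace(2.0, 1.6, len(branch_pts)),
                             parent="LAD"),
        ),
        stenosis=phantom.StenosisSpec(label="LAD", position=0.6,
                                      narrowed_radius=1.2, extent=4.0),
        lungs=(
            phantom.Ellipsoid(center=(64, 64, 14), radii=(60, 55, 12)),
            phantom.Ellipsoid(center=(64, 64, 114), radii=(60, 55, 12)),
        ),
        myocardium=phantom.Ellipsoid(center=(70, 80, 64), radii=(30, 25, 20)),
        aorta=phantom.Cylinder(center_yx=(30, 64), radius=10, z_range=(0, 14)),
        seed=seed,
    )


def _inplane_affine(params) -> register.Affine2D:
    rot_deg, scale, du, dv = params
    a = np.deg2rad(rot_deg)
    r = scale * np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    m = np.eye(3)
    m[:2, :2] = r
    m[2, :2] = (du, dv)
    return register.Affine2D(m)


def make_phantom_pair(cfg: PipelineConfig):
    """Generate the CTA volume, its truth, and the paired angiogram frame.

    Returns ``(vol, truth, angio_img, stenosis_uv, inplane)`` where
    ``stenosis_uv`` is the marked stenosis pixel in the angiogram frame.
    """
    spec = default_phantom_spec(seed=cfg.seed)
    spec = phantom.PhantomSpec3D(
        **{**_spec_kwargs(spec), "noise_sd": cfg.cta_noise_sd, "seed": cfg.seed}
    )
    vol, truth = phantom.make_cta_phantom(spec)
    angles = ViewAngles(*cfg.view)
    geom = phantom.ProjectionGeometry(
        angles=angles,
        center_xyz=tuple(np.asarray(_volume_center(spec.volume_size))),
        image_size=(spec.volume_size[1], spec.volume_size[2]),
    )
    truth.view_to_image = geom
    inplane = _inplane_affine(cfg.inplane)

    img = np.full(geom.image_size, 200.0)
    for label, mask in truth.label_masks.items():
        if label == "Aorta":
            continue
        vox = np.argwhere(mask)
        uv = inplane.transform(geom.project(vox))
        uv = np.rint(uv).astype(int)
        ok = (
            (uv[:, 0] >= 0) & (uv[:, 0] < geom.image_size[1])
            & (uv[:, 1] >= 0) & (uv[:, 1] < geom.image_size[0])
        )
        img[uv[ok, 1], uv[ok, 0]] = 60.0
    if cfg.angio_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img = np.clip(img + rng.normal(0, cfg.angio_noise_sd, img.shape), 0, 255)

    sten_uv = inplane.transform(geom.project([truth.stenosis_voxel]))[0]
    return vol, truth, img, sten_uv, inplane


def _volume_center(shape):
    from .geometry import volume_center

    return volume_center(shape)


def _spec_kwargs(spec):
    return {
        "volume_size": spec.volume_size,
        "tissue_hu": spec.tissue_hu,
        "artery_curves": spec.artery_curves,
        "stenosis": spec.stenosis,
        "lungs": spec.lungs,
        "myocardium": spec.myocardium,
        "aorta": spec.aorta,
        "slope": spec.slope,
        "intercept": spec.intercept,
        "spacing": spec.spacing,
    }


def _select_labels_for(cs, target_mask):
    """Centreline labels whose pixels mostly lie on the target artery.

    Emulates the specialist's label selection using the projected truth.
    """
    chosen = []
    for lab in np.unique(cs.labels):
        if lab == 0:
            continue
        pix = cs.labels == lab
        if np.count_nonzero(pix & target_mask) > 0.5 * np.count_nonzero(pix):
            chosen.append(int(lab))
    return chosen


def _pair_control_points(p_c, p_a):
    """Role-aware correspondence pairing (the specialist's marking).

    The start pairs with the start; end and bifurcation landmarks are
    paired within their role by proximity in normalized coordinates.
    Returns (source, target) arrays for :class:`register.CorrespondenceSet`.
    """
    def _by_role(points, role):
        return [p for p in points if p.role == role]

    src, tgt = [], []
    c_start, a_start = _by_role(p_c, "start"), _by_role(p_a, "start")
    if c_start and a_start:
        src.append((c_start[0].u, c_start[0].v))
        tgt.append((a_start[0].u, a_start[0].v))
    for role in ("end", "bifurcation"):
        c_pts, a_pts = _by_role(p_c, role), _by_role(p_a, role)
        if not (c_pts and a_pts):
            continue
        cn = _normed([(p.u, p.v) for p in p_c], [(p.u, p.v) for p in c_pts])
        an = _normed([(p.u, p.v) for p in p_a], [(p.u, p.v) for p in a_pts])
        used = set()
        for i, c in enumerate(cn):
            d = [np.inf if j in used else np.linalg.norm(c - a) for j, a in enumerate(an)]
            j = int(np.argmin(d))
            if np.isfinite(d[j]):
                used.add(j)
                src.append((c_pts[i].u, c_pts[i].v))
                tgt.append((a_pts[j].u, a_pts[j].v))
    return np.asarray(src, float), np.asarray(tgt, float)


def _normed(all_pts, sub_pts):
    normalized, norm = register.normalize_points(all_pts)
    sub = np.asarray(sub_pts, float)
    return (sub - np.asarray(norm.centroid)) * norm.scale


def run_pipeline(cfg: PipelineConfig = PipelineConfig()) -> PipelineReport:
    """Run phantom generation, both segmentations, registration and the
    3D stenosis localization; score against the phantom truth."""
    vol, truth, angio_img, sten_uv, inplane = make_phantom_pair(cfg)
    geom = truth.view_to_image

    # ---- 2D branch -------------------------------------------------------
    den = angio.denoise_dwt(angio_img)
    seg = angio.segment_main_arteries(den, k=cfg.detail_k, min_length=cfg.min_length)
    cs = angio.extract_centerlines(seg)
    cs = angio.detach_and_label(cs, min_len=cfg.min_len)

    main_label = _stenosed_label(truth)
    tree_vox = np.argwhere(
        np.any([m for k, m in truth.label_masks.items() if k != "Aorta"], axis=0)
    )
    target_uv = inplane.transform(geom.project(tree_vox))
    target_mask = _uv_to_mask(target_uv, seg.shape)
    selected = _select_labels_for(cs, target_mask)
    if not selected:
        raise RuntimeError("no centreline label overlaps the target artery")
    i_a, p_a = angio.label_artery(selected, cs, seg, extend_tips=True)

    # ---- 3D branch -------------------------------------------------------
    hu = ctaseg.to_hounsfield(vol)
    lung_keep = ctaseg.build_lung_mask(hu)
    stack = ctaseg.binarize_slices(hu, lung_keep, method=cfg.binarize, cfg=cfg.track)
    z0, r0, c0 = truth.keypoints[main_label][0][1]
    seed = _snap_seed(stack, ctaseg.Seed(z=z0, row=r0, col=c0, label=main_label))
    model = ctaseg.track_artery(stack, seed, cfg.track)

    # ---- registration ----------------------------------------------------
    proj = register.rotate_and_project(model, geom.angles)
    proj = register.refine_tip_points(proj)
    src, tgt = _pair_control_points(proj.points, p_a)
    if cfg.jitter_px > 0:
        rng = np.random.default_rng(cfg.seed + 7919)
        src = src + rng.normal(0, cfg.jitter_px, src.shape)
        tgt = tgt + rng.normal(0, cfg.jitter_px, tgt.shape)
    corr = register.CorrespondenceSet(source=src, target=tgt)
    t = register.estimate_affine(corr)
    residuals = np.linalg.norm(t.transform(corr.source) - corr.target, axis=1)

    i_r = register.register_artery(i_a, proj, t)
    loc = register.localize_stenosis(i_r, sten_uv, t, tol_px=cfg.tol_px)
    loc = register.back_project(loc, proj, vol.spacing, snap_radius=cfg.snap_radius)

    # ---- scoring against truth ------------------------------------------
    tx, ty, tz = _truth_xyz(truth)
    dist = float(np.linalg.norm(np.subtract(loc.voxel, (tx, ty, tz))))
    dice = evalmetrics.dice(i_a, target_mask)
    rec = evalmetrics.recall(model.M, truth.label_masks[main_label])

    return PipelineReport(
        config=_cfg_dict(cfg),
        transform=[float(v) for v in t.matrix.ravel()],
        residuals_px=[float(r) for r in residuals],
        stenosis_voxel=tuple(int(v) for v in loc.voxel),
        stenosis_mm=tuple(float(v) for v in loc.mm),
        truth_voxel=(tx, ty, tz),
        truth_distance_voxels=dist,
        angio_dice=dice,
        tracking_recall=rec,
        n_control_points=len(corr),
    )


def _stenosed_label(truth):
    # the stenosis voxel lies inside exactly one label mask
    z, y, x = truth.stenosis_voxel
    for label, mask in truth.label_masks.items():
        if label != "Aorta" and mask[z, y, x]:
            return label
    raise RuntimeError("stenosis voxel not inside any artery mask")


def _truth_xyz(truth):
    z, y, x = truth.stenosis_voxel
    return int(x), int(y), int(z)


def _uv_to_mask(uv, shape):
    uv = np.rint(np.asarray(uv)).astype(int)
    ok = (uv[:, 0] >= 0) & (uv[:, 0] < shape[1]) & (uv[:, 1] >= 0) & (uv[:, 1] < shape[0])
    mask = np.zeros(shape, dtype=bool)
    mask[uv[ok, 1], uv[ok, 0]] = True
    return mask


def _snap_seed(stack, seed):
    if stack[seed.z, seed.row, seed.col]:
        return seed
    pts = np.argwhere(stack[seed.z])
    if len(pts) == 0:
        raise RuntimeError(f"no vessel candidate in seed slice {seed.z}")
    i = int(np.argmin(((pts - [seed.row, seed.col]) ** 2).sum(axis=1)))
    return ctaseg.Seed(z=seed.z, row=int(pts[i][0]), col=int(pts[i][1]),
                       label=seed.label)


def _cfg_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["track"] = asdict(cfg.track)
    return d
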