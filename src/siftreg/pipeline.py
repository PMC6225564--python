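"""The full two-stage feature-based registration pipeline.

Stage order, with the physical-distance parameters in mm:

1. normalize intensities and extract 3D SIFT features from both volumes;
2. global mutual nearest-neighbor descriptor matching;
3. affine RANSAC with a deliberately high 10 mm inlier threshold (the
   true CBCT->CT map is affine plus a small nonlinear residual);
4. prune CT features outside the stage-1-transformed CBCT field of view
   (plus a small margin), then re-match locally within a 10 mm radius of
   each feature's transformed position;
5. affine RANSAC again at a tighter 5 mm threshold;
6. thin-plate spline fitted on the stage-2 inlier correspondences.

All estimated maps take CBCT physical points into CT physical space.
A stage that cannot continue (fewer than 4 usable matches, no RANSAC
consensus) produces an explicit failure result that names the failing
stage and keeps everything computed so far.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matching import local_match, mutual_match, prune_to_fov
from .sift3d import FeatureSet, extract_features
from .transforms import (
    AffineTransform3D,
    TPSTransform3D,
    fit_tps,
    invert_affine,
    invert_map_points,
    ransac_affine,
    transform_to_dict,
)
from .volume_io import Volume, resample_into

__all__ = ["RegistrationConfig", "RegistrationResult", "register", "fuse", "checkerboard"]

logger = logging.getLogger(__name__)


@dataclass
class RegistrationConfig:
    """All tunable parameters of the registration pipeline (distances in mm)."""

    stage1_threshold: float = 10.0  # RANSAC inlier threshold, stage 1
    stage2_threshold: float = 5.0  # RANSAC inlier threshold, stage 2
    local_radius: float = 10.0  # stage-2 local search radius
    fov_margin: float = 10.0  # dilation of the transformed CBCT FOV
    working_spacing: float = 2.0  # isotropic grid for feature extraction
    sigma0_voxels: float = 1.6
    levels_per_octave: int = 3
    contrast_threshold: float = 0.02
    edge_threshold: float = 10.0
    max_features: int = 20000
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    ransac_confidence: float = 0.99
    ransac_max_iterations: int = 10000
    # Smoothing-spline stiffness (kernel units, mm).  The residual motion
    # the TPS must capture is smooth and organ-scale (several centimetres);
    # individual correspondences carry localization noise and occasional
    # sub-threshold mismatches.  A stiff spline resolves the former and
    # averages out the latter; 0 gives the pure interpolating spline.
    tps_regularization: float = 300.0
    max_tps_points: int = 800
    seed: int = 0

    def __post_init__(self):
        for name in ("stage1_threshold", "stage2_threshold", "local_radius",
                     "fov_margin", "working_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (mm)")
        if self.stage2_threshold > self.stage1_threshold:
            raise ValueError("stage2_threshold must be <= stage1_threshold")

    @classmethod
    def from_json(cls, path) -> "RegistrationConfig":
        """Load a config; unspecified keys keep their documented defaults."""
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


@dataclass
class RegistrationResult:
    """Per-stage transforms and diagnostics of one registration run."""

    affine_stage1: AffineTransform3D | None = None
    affine_stage2: AffineTransform3D | None = None
    tps: TPSTransform3D | None = None
    counts: dict = field(default_factory=dict)
    status: str = "failure"
    failed_stage: str | None = None
    message: str = ""

    @property
    def success(self) -> bool:
        return self.status == "success"

    @property
    def final_map(self):
        """The best available CBCT->CT map (TPS, else stage-2/1 affine)."""
        for t in (self.tps, self.affine_stage2, self.affine_stage1):
            if t is not None:
                return t
        raise ValueError("registration produced no transform")

    def to_dict(self) -> dict:
        d = {
            "status": self.status,
            "failed_stage": self.failed_stage,
            "message": self.message,
            "counts": dict(self.counts),
        }
        for name in ("affine_stage1", "affine_stage2", "tps"):
            t = getattr(self, name)
            d[name] = None if t is None else transform_to_dict(t)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _extract(volume: Volume, config: RegistrationConfig) -> FeatureSet:
    return extract_features(
        volume,
        working_spacing=config.working_spacing,
        sigma0_voxels=config.sigma0_voxels,
        levels_per_octave=config.levels_per_octave,
        contrast_threshold=config.contrast_threshold,
        edge_threshold=config.edge_threshold,
        max_features=config.max_features,
        lower_percentile=config.lower_percentile,
        upper_percentile=config.upper_percentile,
    )


def register(ct: Volume, cbct: Volume, config: RegistrationConfig | None = None) -> RegistrationResult:
    """Run the full two-stage feature-based registration (CBCT -> CT).

    Deterministic for a fixed ``config.seed``.  Returns a
    :class:`RegistrationResult`; on failure the result carries the stages
    completed so far and the name of the failing stage.
    """
    config = config or RegistrationConfig()
    result = RegistrationResult()

    def fail(stage: str, message: str) -> RegistrationResult:
        result.status = "failure"
        result.failed_stage = stage
        result.message = message
        logger.warning("registration failed at %s: %s", stage, message)
        return result

    feats_ct = _extract(ct, config)
    feats_cbct = _extract(cbct, config)
    result.counts["n_features_ct"] = len(feats_ct)
    result.counts["n_features_cbct"] = len(feats_cbct)
    logger.info("features: CT %d, CBCT %d", len(feats_ct), len(feats_cbct))
    if len(feats_ct) < 4 or len(feats_cbct) < 4:
        return fail("feature_detection", "fewer than 4 features in a volume")

    matches = mutual_match(feats_cbct, feats_ct)
    result.counts["n_mutual_matches"] = len(matches)
    logger.info("mutual matches: %d", len(matches))
    if len(matches) < 4:
        return fail("mutual_match", f"only {len(matches)} mutual matches")

    pa = feats_cbct.positions[matches.pairs[:, 0]]
    pb = feats_ct.positions[matches.pairs[:, 1]]
    r1 = ransac_affine(pa, pb, config.stage1_threshold,
                       config.ransac_confidence, config.ransac_max_iterations,
                       seed=config.seed)
    result.counts["n_stage1_inliers"] = r1.n_inliers
    if not r1.success:
        return fail("ransac_stage1", "no affine consensus at the 10 mm stage")
    det1 = np.linalg.det(r1.transform.linear)
    if not (0.5 <= abs(det1) <= 2.0):
        return fail("ransac_stage1", f"implausible affine determinant {det1:.3g}")
    result.affine_stage1 = r1.transform
    logger.info("stage-1 RANSAC: %d/%d inliers in %d iterations",
                r1.n_inliers, len(matches), r1.n_iterations)

    pruned_ct, kept_idx = prune_to_fov(feats_ct, cbct, r1.transform, config.fov_margin)
    result.counts["n_ct_features_in_fov"] = len(pruned_ct)
    logger.info("CT features inside transformed CBCT FOV (+%g mm): %d",
                config.fov_margin, len(pruned_ct))
    if len(pruned_ct) < 4:
        return fail("fov_pruning", "fewer than 4 CT features inside the FOV")

    local = local_match(feats_cbct, pruned_ct, r1.transform, config.local_radius)
    result.counts["n_local_matches"] = len(local)
    logger.info("local matches within %g mm: %d", config.local_radius, len(local))
    if len(local) < 4:
        return fail("local_match", f"only {len(local)} local matches")

    pa2 = feats_cbct.positions[local.pairs[:, 0]]
    pb2 = pruned_ct.positions[local.pairs[:, 1]]
    r2 = ransac_affine(pa2, pb2, config.stage2_threshold,
                       config.ransac_confidence, config.ransac_max_iterations,
                       seed=config.seed + 1)
    result.counts["n_stage2_inliers"] = r2.n_inliers
    if not r2.success:
        return fail("ransac_stage2", "no affine consensus at the 5 mm stage")
    result.affine_stage2 = r2.transform
    logger.info("stage-2 RANSAC: %d/%d inliers in %d iterations",
                r2.n_inliers, len(local), r2.n_iterations)

    det = np.linalg.det(r2.transform.linear)
    if not (0.5 <= abs(det) <= 2.0):
        return fail("ransac_stage2", f"implausible affine determinant {det:.3g}")

    src = pa2[r2.inlier_mask]
    tgt = pb2[r2.inlier_mask]
    src, tgt = _dedupe_control_points(src, tgt)
    if len(src) > config.max_tps_points:
        sel = np.random.default_rng(config.seed + 2).choice(
            len(src), size=config.max_tps_points, replace=False)
        sel.sort()
        src, tgt = src[sel], tgt[sel]
    result.counts["n_tps_control_points"] = len(src)
    try:
        result.tps = fit_tps(src, tgt, config.tps_regularization)
    except ValueError as exc:
        return fail("tps_fit", str(exc))

    result.status = "success"
    result.failed_stage = None
    return result


def _dedupe_control_points(src: np.ndarray, tgt: np.ndarray, tol: float = 1e-6):
    """Drop correspondences whose source points coincide within ``tol`` mm
    (TPS requires distinct control points); the first occurrence wins."""
    if len(src) == 0:
        return src, tgt
    key = np.round(src / tol).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    first.sort()
    return src[first], tgt[first]


def fuse(ct: Volume, cbct: Volume, result: RegistrationResult,
         fill_value: float = 0.0, interpolation: str = "linear") -> Volume:
    """Resample the CBCT onto the CT grid through the final registration map.

    The estimated maps run CBCT->CT, so fusion needs the inverse: the TPS
    is inverted numerically per voxel (quasi-Newton fixed point, stage-2
    affine as initializer).  Voxels where the inversion does not converge
    fall back to the stage-2 affine inverse; if more than 1% of the mapped
    voxels do so, a warning is recorded.
    """
    if not result.success:
        raise ValueError("fuse requires a successful registration result")
    final = result.final_map
    if isinstance(final, AffineTransform3D):
        return resample_into(cbct, invert_affine(final), ct,
                             interpolation=interpolation, fill_value=fill_value)

    affine = result.affine_stage2 or result.affine_stage1
    affine_inv = invert_affine(affine)
    pts = ct.grid_points().reshape(-1, 3)
    # Only invert where the affine preimage lands anywhere near the CBCT
    # grid; everything else is fill anyway.
    pre = affine_inv.transform_points(pts)
    idx = cbct.physical_to_voxel(pre)
    shape = np.asarray(cbct.shape)
    margin = 20.0 / cbct.spacing
    near = np.all((idx >= -0.5 - margin) & (idx <= shape - 0.5 + margin), axis=1)

    mapped = pre.copy()
    n_bad = 0
    sel = np.nonzero(near)[0]
    chunk = 200_000
    for start in range(0, len(sel), chunk):
        block = sel[start : start + chunk]
        p, conv = invert_map_points(final, pts[block], initializer=affine,
                                    max_iter=30, tol=1e-3)
        p[~conv] = pre[block][~conv]  # affine fallback
        n_bad += int((~conv).sum())
        mapped[block] = p
    if len(sel) and n_bad > 0.01 * len(sel):
        warnings.warn(
            f"TPS inversion fell back to the affine at {n_bad}/{len(sel)} voxels",
            RuntimeWarning,
        )

    from scipy.ndimage import map_coordinates

    coords = cbct.physical_to_voxel(mapped).T
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = map_coordinates(cbct.data.astype(float), coords, order=order,
                          mode="constant", cval=fill_value)
    return ct.with_data(out.reshape(ct.shape))


def checkerboard(a: Volume, b: Volume, tile: int = 16) -> Volume:
    """Alternating tiles from two volumes on the same grid (visual QC)."""
    if a.shape != b.shape or not (
        np.allclose(a.spacing, b.spacing)
        and np.allclose(a.origin, b.origin)
        and np.allclose(a.direction, b.direction)
    ):
        raise ValueError("checkerboard requires volumes on the same grid")
    if tile <= 0:
        raise ValueError("tile size must be positive")
    ix, iy, iz = np.indices(a.shape) // tile
    mask = (ix + iy + iz) % 2 == 0
    return a.with_data(np.where(mask, a.data, b.data))
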