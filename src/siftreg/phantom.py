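"""Synthetic CT/CBCT pairs with known ground truth.

The generator emulates the acquisition differences that make CTA-to-CBCT
registration hard: a preoperative "CT" covering roughly three times the
field of view of the intraoperative "CBCT" (a 25 cm diameter x 19 cm tall
reconstruction cylinder), an inter-acquisition pose change (rigid rotation
and translation plus a small scale), a smooth low-frequency nonlinear
deformation of a few millimetres, uncalibrated CBCT intensities (gain and
offset relative to CT plus noise), and a contrast-filled aorta that exists
only in the CT.

The scene is abdominal-aorta-like without any pretence of X-ray physics:
a soft-tissue body ellipse with band-limited texture, a column of bright
vertebra-like bodies with spinous/transverse processes, an aorta tube
(contrast-bright in CT, near-isointense in CBCT), and small bright
calcification spots on the aorta wall that are visible in both modalities.
Landmarks are three calcification centers and three vertebral anterior
points, mirroring the "vascular calcifications and bony structures" used
for clinical validation.

The ground-truth CBCT-to-CT map (affine plus a sum of wide Gaussian
displacement bumps) is analytic and evaluable at any physical point, so
registration accuracy can be measured exactly anywhere, not just at the
stored landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .transforms import AffineTransform3D, invert_map_points
from .volume_io import Volume, resample_into

__all__ = ["PhantomSpec", "PhantomMap", "PhantomPair", "generate_phantom_pair", "true_error_field"]

# Scene intensities (arbitrary HU-like units)
_SOFT_TISSUE = 40.0
_VERTEBRA = 700.0
_AORTA_CONTRAST = 1100.0
_AORTA_PLAIN = 60.0
_CALCIFICATION_AMP = 800.0
_TEXTURE_SD = 25.0


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic pair; ``seed`` fixes all randomness."""

    ct_extent: tuple = (360.0, 360.0, 480.0)  # mm
    ct_spacing: float = 2.0  # mm, isotropic (clinical CT is finer; see docs)
    cbct_fov: tuple = (250.0, 190.0)  # cylinder diameter, height (mm)
    cbct_spacing: float = 2.0  # mm (clinical CBCT is 0.5 mm isotropic)
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 30.0
    max_scale_change: float = 0.03
    nonlinear_amplitude: float = 5.0  # mm, peak smooth-warp displacement
    intensity_gain: float = 0.6
    intensity_offset: float = 100.0
    noise_sd: float = 20.0  # additive CBCT noise, scene units
    ct_noise_sd: float = 5.0  # mild CT acquisition noise, scene units
    n_vertebrae: int = 15
    n_calcifications: int = 8
    include_aorta_contrast: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.nonlinear_amplitude < 0:
            raise ValueError("nonlinear_amplitude must be >= 0")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if min(self.ct_extent) <= 0 or self.ct_spacing <= 0 or self.cbct_spacing <= 0:
            raise ValueError("extents and spacings must be positive")
        if self.n_calcifications < 3:
            raise ValueError("need at least 3 calcifications (3 are landmarks)")
        # Coarse feasibility check: even with the most favorable pose the
        # CBCT cylinder must fit inside the CT box.  The sampled map is
        # additionally checked exactly (and resampled) during generation.
        r = self.cbct_fov[0] / 2.0
        h = self.cbct_fov[1] / 2.0
        half = np.asarray(self.ct_extent) / 2.0
        if r > min(half[0], half[1]) or h > half[2]:
            raise ValueError("CBCT field of view cannot fit inside the CT extent")


class PhantomMap:
    """Analytic ground-truth CBCT->CT map: affine plus Gaussian displacement bumps.

    T(p) = A p + t + sum_k a_k exp(-||p - c_k||^2 / (2 s_k^2))
    """

    def __init__(self, linear, translation, bump_centers, bump_sigmas, bump_amps):
        self.affine = AffineTransform3D(linear, translation)
        self.bump_centers = np.asarray(bump_centers, dtype=float).reshape(-1, 3)
        self.bump_sigmas = np.asarray(bump_sigmas, dtype=float).reshape(-1)
        self.bump_amps = np.asarray(bump_amps, dtype=float).reshape(-1, 3)

    @property
    def linear(self):
        return self.affine.linear

    @property
    def translation(self):
        return self.affine.translation

    def displacement(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        disp = np.zeros_like(points)
        for c, s, a in zip(self.bump_centers, self.bump_sigmas, self.bump_amps):
            r2 = np.sum((points - c) ** 2, axis=1)
            disp += np.exp(-r2 / (2.0 * s**2))[:, None] * a
        return disp

    def transform_points(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        out = self.affine.transform_points(pts) + self.displacement(pts)
        return out[0] if single else out

    def __call__(self, points):
        return self.transform_points(points)

    def inverse_points(self, targets, tol: float = 1e-9):
        pts, conv = invert_map_points(self, np.atleast_2d(targets),
                                      initializer=self.affine, max_iter=200, tol=tol)
        return pts, conv

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.ravel().tolist(),
            "translation": self.translation.tolist(),
            "bump_centers": self.bump_centers.tolist(),
            "bump_sigmas": self.bump_sigmas.tolist(),
            "bump_amps": self.bump_amps.tolist(),
        }

    @classmethod
    def from_dict(cls, d) -> "PhantomMap":
        return cls(np.asarray(d["linear"]).reshape(3, 3), d["translation"],
                   d["bump_centers"], d["bump_sigmas"], d["bump_amps"])


@dataclass
class PhantomPair:
    ct: Volume
    cbct: Volume
    true_map: PhantomMap
    landmarks_ct: dict  # label -> (3,) mm, CT physical space
    landmarks_cbct: dict  # label -> (3,) mm, CBCT physical space
    spec: PhantomSpec = field(default=None)


def _rotation_matrix(axis, angle) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _cylinder_boundary(spec: PhantomSpec) -> np.ndarray:
    """Sample points on the CBCT reconstruction cylinder boundary."""
    r = spec.cbct_fov[0] / 2.0
    h = spec.cbct_fov[1] / 2.0
    theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    rings = []
    for z in (-h, 0.0, h):
        rings.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                      np.full_like(theta, z)]))
    rings.append(np.array([[0.0, 0.0, -h], [0.0, 0.0, h]]))
    return np.vstack(rings)


def _sample_true_map(spec: PhantomSpec, rng: np.random.Generator) -> PhantomMap:
    """Draw a ground-truth map; redraw (same stream) until the mapped CBCT
    cylinder lies inside the CT extent, so every generated pair is valid."""
    boundary = _cylinder_boundary(spec)
    half = np.asarray(spec.ct_extent) / 2.0
    for _ in range(100):
        m = _sample_one_map(spec, rng)
        mapped = m.transform_points(boundary)
        if np.all(np.abs(mapped) <= half):
            return m
    raise ValueError("CBCT field of view cannot fit inside the CT extent "
                     "under the allowed pose change")


def _sample_one_map(spec: PhantomSpec, rng: np.random.Generator) -> PhantomMap:
    angle = np.deg2rad(spec.max_rotation_deg) * rng.uniform(0.0, 1.0)
    axis = rng.normal(size=3)
    scale = 1.0 + rng.uniform(-spec.max_scale_change, spec.max_scale_change)
    A = scale * _rotation_matrix(axis, angle)
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    t = t_dir * spec.max_translation_mm * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)

    if spec.nonlinear_amplitude > 0:
        n_bumps = 4
        centers = np.column_stack([
            rng.uniform(-100, 100, n_bumps),
            rng.uniform(-100, 100, n_bumps),
            rng.uniform(-80, 80, n_bumps),
        ])
        sigmas = rng.uniform(40.0, 70.0, n_bumps)
        amps = rng.normal(size=(n_bumps, 3))
        m = PhantomMap(A, t, centers, sigmas, amps)
        # Rescale so the peak displacement over the CBCT FOV hits the
        # requested amplitude (sampled fraction of the cap).
        r = spec.cbct_fov[0] / 2.0
        h = spec.cbct_fov[1] / 2.0
        g = np.linspace(-1, 1, 13)
        gx, gy, gz = np.meshgrid(g * r, g * r, g * h, indexing="ij")
        probe = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        peak = np.linalg.norm(m.displacement(probe), axis=1).max()
        target = spec.nonlinear_amplitude * rng.uniform(0.6, 1.0)
        m.bump_amps *= target / max(peak, 1e-12)
        return m
    return PhantomMap(A, t, np.zeros((0, 3)), np.zeros(0), np.zeros((0, 3)))


def _paint_scene(spec: PhantomSpec, rng: np.random.Generator):
    """Paint the CT-frame scene on the CT grid.

    Returns ``(base, contrast, landmarks_ct)`` where ``base`` is the scene
    without aortic contrast (the tissue the CBCT sees) and ``contrast`` is
    the CT appearance.  Both are noiseless; modality noise is added later.
    """
    extent = np.asarray(spec.ct_extent)
    shape = np.maximum(2, np.round(extent / spec.ct_spacing)).astype(int)
    origin = -(shape - 1) / 2.0 * spec.ct_spacing
    # axis coordinate vectors (direction = identity)
    xs = origin[0] + np.arange(shape[0]) * spec.ct_spacing
    ys = origin[1] + np.arange(shape[1]) * spec.ct_spacing
    zs = origin[2] + np.arange(shape[2]) * spec.ct_spacing
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    grid = np.zeros(tuple(shape), dtype=np.float32)

    # Soft-tissue body: elliptical cylinder with a smooth edge.
    body_q = np.sqrt((X / 160.0) ** 2 + (Y / 130.0) ** 2) + 0 * Z
    body = np.clip((1.05 - body_q) / 0.05, 0.0, 1.0).astype(np.float32)
    grid += _SOFT_TISSUE * body

    # Band-limited soft-tissue texture (filtered white noise).
    tex = rng.standard_normal(tuple(shape)).astype(np.float32)
    tex = ndimage.gaussian_filter(tex, 2.5, mode="nearest")
    tex *= _TEXTURE_SD / max(tex.std(), 1e-9)
    grid += tex * body

    def paint_ellipsoid(center, semiaxes, value, edge=0.15):
        lo = np.maximum(np.floor((center - semiaxes * (1 + edge) - origin) / spec.ct_spacing).astype(int), 0)
        hi = np.minimum(np.ceil((center + semiaxes * (1 + edge) - origin) / spec.ct_spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            return
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        q = np.sqrt(
            ((xs[sl[0]][:, None, None] - center[0]) / semiaxes[0]) ** 2
            + ((ys[sl[1]][None, :, None] - center[1]) / semiaxes[1]) ** 2
            + ((zs[sl[2]][None, None, :] - center[2]) / semiaxes[2]) ** 2
        )
        w = np.clip((1.0 + edge - q) / edge, 0.0, 1.0).astype(np.float32)
        region = grid[sl]
        np.maximum(region, w * value + (1 - w) * region, out=region)

    # Vertebral column: bodies + spinous and transverse processes.
    y_spine = 45.0
    n_vert = spec.n_vertebrae
    pitch = 30.0
    z0 = -(n_vert - 1) / 2.0 * pitch
    body_semi = np.array([17.0, 13.0, 11.0])
    vert_z = z0 + pitch * np.arange(n_vert)
    for zc in vert_z:
        c = np.array([0.0, y_spine, zc])
        paint_ellipsoid(c, body_semi, _VERTEBRA)
        paint_ellipsoid(c + [0.0, 24.0, 0.0], np.array([5.0, 12.0, 5.0]), _VERTEBRA)
        paint_ellipsoid(c + [20.0, 8.0, 0.0], np.array([12.0, 4.0, 4.0]), _VERTEBRA)
        paint_ellipsoid(c + [-20.0, 8.0, 0.0], np.array([12.0, 4.0, 4.0]), _VERTEBRA)

    # Aorta: a gently curving vertical tube anterior to the spine.
    aorta_y = 10.0
    aorta_r = 11.0
    def aorta_xc(z):
        return 8.0 * np.sin(2.0 * np.pi * (z + extent[2] / 2.0) / 400.0)
    xc = aorta_xc(zs)  # (nz,)
    r_t = np.sqrt((X - xc[None, None, :]) ** 2 + (Y - aorta_y) ** 2)
    tube_w = np.clip((aorta_r - r_t) / 1.5 + 0.5, 0.0, 1.0).astype(np.float32)

    base = grid.copy()
    base += tube_w * (_AORTA_PLAIN - base) * (base < _VERTEBRA * 0.5)
    contrast_val = _AORTA_CONTRAST if spec.include_aorta_contrast else _AORTA_PLAIN
    grid += tube_w * (contrast_val - grid) * (grid < _VERTEBRA * 0.5)

    # Calcifications on the aorta wall (Gaussian spots, 1.5-3 mm sigma).
    landmarks_ct: dict[str, np.ndarray] = {}
    calc_z = [-40.0, 0.0, 40.0] + list(rng.uniform(-100.0, 100.0, spec.n_calcifications - 3))
    for i, czc in enumerate(calc_z):
        theta = rng.uniform(0, 2 * np.pi)
        center = np.array([
            aorta_xc(czc) + aorta_r * np.cos(theta),
            aorta_y + aorta_r * np.sin(theta),
            czc,
        ])
        sig = rng.uniform(1.5, 3.0)
        lo = np.maximum(np.floor((center - 4 * sig - origin) / spec.ct_spacing).astype(int), 0)
        hi = np.minimum(np.ceil((center + 4 * sig - origin) / spec.ct_spacing).astype(int) + 1, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        r2 = (
            (xs[sl[0]][:, None, None] - center[0]) ** 2
            + (ys[sl[1]][None, :, None] - center[1]) ** 2
            + (zs[sl[2]][None, None, :] - center[2]) ** 2
        )
        blob = (_CALCIFICATION_AMP * np.exp(-r2 / (2 * sig**2))).astype(np.float32)
        base[sl] += blob
        grid[sl] += blob
        if i < 3:
            landmarks_ct[f"calc_{i + 1}"] = center

    # Vertebral landmarks: anterior face midpoints of the 3 central bodies.
    central = np.argsort(np.abs(vert_z))[:3]
    for i, k in enumerate(sorted(central)):
        landmarks_ct[f"vert_{i + 1}"] = np.array([0.0, y_spine - body_semi[1], vert_z[k]])

    ct_grid = Volume(grid, np.full(3, spec.ct_spacing), origin, np.eye(3))
    base_grid = Volume(base, np.full(3, spec.ct_spacing), origin, np.eye(3))
    return base_grid, ct_grid, landmarks_ct


def generate_phantom_pair(spec: PhantomSpec | None = None) -> PhantomPair:
    """Generate a CT/CBCT pair, ground-truth map, and paired landmarks.

    The CT is the painted scene (with aortic contrast by default) plus mild
    acquisition noise.  The CBCT samples the *non-contrast* scene through
    the ground-truth map at every voxel of its own grid, crops to the
    cylindrical reconstruction FOV, and applies the intensity gain/offset
    and additive noise.  Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    true_map = _sample_true_map(spec, rng)
    base, ct_scene, landmarks_ct = _paint_scene(spec, rng)

    ct_data = ct_scene.data
    if spec.ct_noise_sd > 0:
        ct_data = ct_data + rng.normal(0, spec.ct_noise_sd, ct_scene.shape).astype(np.float32)
    ct = ct_scene.with_data(ct_data)

    # CBCT grid: centered on its own world origin; the pose change lives
    # entirely in true_map.
    diam, height = spec.cbct_fov
    cbct_shape = np.maximum(2, np.round(np.array([diam, diam, height]) / spec.cbct_spacing)).astype(int)
    cbct_origin = -(cbct_shape - 1) / 2.0 * spec.cbct_spacing
    reference = Volume(np.zeros(tuple(cbct_shape), dtype=np.float32),
                       np.full(3, spec.cbct_spacing), cbct_origin, np.eye(3))
    cbct_vol = resample_into(base, true_map, reference, interpolation="linear",
                             fill_value=0.0)
    data = cbct_vol.data * spec.intensity_gain + spec.intensity_offset
    if spec.noise_sd > 0:
        data = data + rng.normal(0, spec.noise_sd, data.shape)
    # Cylindrical reconstruction FOV: voxels outside the cylinder are empty.
    xs = cbct_origin[0] + np.arange(cbct_shape[0]) * spec.cbct_spacing
    ys = cbct_origin[1] + np.arange(cbct_shape[1]) * spec.cbct_spacing
    rr = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    cyl = (rr <= diam / 2.0)[:, :, None]
    data = np.where(cyl, data, 0.0).astype(np.float32)
    cbct = reference.with_data(data)

    # CBCT landmarks: pull the CT landmarks back through the ground truth.
    landmarks_cbct: dict[str, np.ndarray] = {}
    labels = sorted(landmarks_ct)
    pts, conv = true_map.inverse_points(np.array([landmarks_ct[k] for k in labels]), tol=1e-9)
    if not conv.all():
        raise RuntimeError("ground-truth map inversion failed at a landmark")
    for k, p in zip(labels, pts):
        r_xy = np.hypot(p[0], p[1])
        if r_xy > diam / 2.0 - 2.0 or abs(p[2]) > height / 2.0 - 2.0:
            raise RuntimeError(f"landmark {k} falls outside the CBCT FOV")
        landmarks_cbct[k] = p

    return PhantomPair(ct, cbct, true_map, landmarks_ct, landmarks_cbct, spec)


def true_error_field(pair: PhantomPair, estimated, sample_points) -> np.ndarray:
    """Residual ||estimated(p) - true_map(p)|| (mm) at each sample point.

    ``estimated`` is any CBCT->CT map (affine, TPS, or callable); sample
    points are CBCT physical coordinates, normally inside the CBCT FOV.
    """
    from .transforms import apply_transform

    pts = np.atleast_2d(np.asarray(sample_points, dtype=float))
    est = apply_transform(estimated, pts)
    true = pair.true_map.transform_points(pts)
    return np.linalg.norm(est - true, axis=1)


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> PhantomSpec:
    spec = PhantomSpec()
    for k, v in d.items():
        if not hasattr(spec, k):
            raise ValueError(f"unknown phantom spec field {k!r}")
        setattr(spec, k, tuple(v) if isinstance(getattr(spec, k), tuple) else v)
    return spec
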