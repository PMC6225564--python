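"""3D SIFT: scale-space keypoint detection and gradient-histogram descriptors.

The classic difference-of-Gaussians (DoG) keypoint pipeline lifted to
volumes: an octave pyramid of Gaussian-smoothed grids, extrema of the DoG
over the 3x3x3x3 scale-space neighborhood (80 neighbors), sub-voxel
refinement by a quadratic fit, contrast and edge/plate rejection, and a
descriptor that accumulates gradient magnitudes into a 4x4x4 grid of
spatial subregions times 12 solid-angle orientation bins (length 768),
clipped at 0.2 and renormalized to unit norm.

Descriptors are computed in the volume axes without per-keypoint
orientation assignment: the intended use is intra-patient CT/CBCT
registration where pose differences are small rotations, which the
affine RANSAC stage absorbs.  Large rotations are a documented
limitation.

Keypoint positions and scales are physical (mm), so features detected on
grids of different resolution are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume, resample_into

__all__ = [
    "DESCRIPTOR_SPATIAL_BINS",
    "DESCRIPTOR_ORIENT_BINS",
    "DESCRIPTOR_LENGTH",
    "FeatureSet",
    "ScaleSpace",
    "normalize_intensities",
    "resample_isotropic",
    "build_scale_space",
    "detect_keypoints",
    "compute_descriptors",
    "extract_features",
]

logger = logging.getLogger(__name__)

# Descriptor geometry: 4x4x4 spatial subregions x 12 solid-angle bins.
DESCRIPTOR_SPATIAL_BINS = 4
DESCRIPTOR_ORIENT_BINS = 12
DESCRIPTOR_LENGTH = DESCRIPTOR_SPATIAL_BINS**3 * DESCRIPTOR_ORIENT_BINS
_DESCRIPTOR_CLIP = 0.2


def _icosahedron_vertices() -> np.ndarray:
    """12 unit vectors (icosahedron vertices) used as orientation bin centers."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    v = np.asarray(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


_ORIENT_DIRS = _icosahedron_vertices()


class DegenerateInputError(ValueError):
    pass


class VolumeTooSmallError(ValueError):
    pass


def normalize_intensities(
    volume: Volume, lower_percentile: float = 1.0, upper_percentile: float = 99.0
) -> Volume:
    """Map intensities to [0, 1] by robust percentile scaling.

    Values are clipped at the given percentiles then rescaled linearly, so
    the result is invariant to any positive affine intensity map a*I + b.
    This is the intensity bridge between HU-like CT values and uncalibrated
    CBCT values.

    Raises
    ------
    DegenerateInputError
        If the volume has fewer than two distinct intensities.
    """
    data = volume.data.astype(float)
    lo, hi = np.percentile(data, [lower_percentile, upper_percentile])
    if hi <= lo:
        lo, hi = data.min(), data.max()
    if hi <= lo:
        raise DegenerateInputError("constant volume: cannot normalize intensities")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return volume.with_data(out)


def resample_isotropic(volume: Volume, spacing_mm: float, interpolation: str = "linear") -> Volume:
    """Resample a volume onto an isotropic grid with the same physical extent.

    Scale-space sigmas are expressed in mm; on anisotropic grids (clinical
    CT slice thickness commonly differs from in-plane spacing) that is only
    meaningful after resampling to a common isotropic resolution.
    """
    if np.allclose(volume.spacing, spacing_mm):
        return volume
    extent = np.asarray(volume.shape) * volume.spacing
    new_shape = np.maximum(2, np.round(extent / spacing_mm).astype(int))
    # Keep the physical center fixed; voxel centers lie at origin + k*spacing.
    center = volume.voxel_to_physical((np.asarray(volume.shape) - 1) / 2.0)
    new_origin = center - volume.direction @ ((new_shape - 1) / 2.0 * spacing_mm)
    reference = Volume(
        np.zeros(tuple(new_shape)),
        np.full(3, float(spacing_mm)),
        new_origin,
        volume.direction,
    )
    return resample_into(volume, None, reference, interpolation=interpolation)


@dataclass
class Octave:
    gaussians: list  # Gaussian-smoothed grids, len = levels_per_octave + 3
    dogs: list  # adjacent-level differences, len = levels_per_octave + 2
    sigmas_mm: np.ndarray  # absolute sigma of each Gaussian level, mm
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def voxel_to_physical(self, index):
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T


@dataclass
class ScaleSpace:
    octaves: list
    levels_per_octave: int
    sigma0_mm: float


@dataclass
class FeatureSet:
    """Keypoints with index-aligned descriptors, stored as flat arrays.

    ``positions`` are physical mm; ``scales`` are detection sigmas in mm;
    ``responses`` are refined DoG values at the extremum; descriptors are
    unit-norm rows (or all-zero for degenerate flat neighborhoods).
    """

    positions: np.ndarray  # (N, 3) mm
    scales: np.ndarray  # (N,) mm
    responses: np.ndarray  # (N,)
    descriptors: np.ndarray  # (N, DESCRIPTOR_LENGTH)
    octaves: np.ndarray = field(default=None)  # (N,) int
    levels: np.ndarray = field(default=None)  # (N,) int

    def __post_init__(self):
        n = len(self.positions)
        if self.octaves is None:
            self.octaves = np.zeros(n, dtype=int)
        if self.levels is None:
            self.levels = np.zeros(n, dtype=int)
        for name in ("positions", "scales", "responses", "descriptors", "octaves", "levels"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.scales) == len(self.responses) == len(self.descriptors) == n
        ):
            raise ValueError("FeatureSet arrays must be index-aligned")

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, indices) -> "FeatureSet":
        indices = np.asarray(indices)
        return FeatureSet(
            self.positions[indices],
            self.scales[indices],
            self.responses[indices],
            self.descriptors[indices],
            self.octaves[indices],
            self.levels[indices],
        )

    @classmethod
    def empty(cls) -> "FeatureSet":
        return cls(
            np.zeros((0, 3)),
            np.zeros(0),
            np.zeros(0),
            np.zeros((0, DESCRIPTOR_LENGTH)),
        )

    def to_csv(self, path) -> None:
        """Tabular serialization: x,y,z,scale,response,d0..d{K-1}."""
        k = self.descriptors.shape[1] if len(self) else DESCRIPTOR_LENGTH
        header = "x,y,z,scale,response," + ",".join(f"d{i}" for i in range(k))
        table = np.hstack(
            [
                self.positions,
                self.scales[:, None],
                self.responses[:, None],
                self.descriptors,
            ]
        )
        np.savetxt(path, table, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "FeatureSet":
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if table.size == 0:
            return cls.empty()
        return cls(table[:, :3], table[:, 3], table[:, 4], table[:, 5:])


def build_scale_space(
    volume: Volume,
    n_octaves: int | None = None,
    levels_per_octave: int = 3,
    sigma0_mm: float | None = None,
    assumed_blur_voxels: float = 0.5,
) -> ScaleSpace:
    """Build a Gaussian/DoG octave pyramid.

    Within an octave the absolute sigma follows the geometric schedule
    ``sigma0 * 2**(l / levels_per_octave)``; each octave holds
    ``levels_per_octave + 3`` Gaussian levels so extrema can be located in
    ``levels_per_octave`` DoG slices.  Octaves are downsampled by taking
    every second voxel; by default octaves are added until the next one
    would have a minimum axis below 16 voxels.

    ``sigma0_mm`` defaults to 1.6 voxels of the (isotropic) input grid.
    """
    spacing = volume.spacing
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        raise ValueError("build_scale_space expects an isotropic grid; resample first")
    h = float(spacing[0])
    if sigma0_mm is None:
        sigma0_mm = 1.6 * h

    shape = np.asarray(volume.shape)
    if n_octaves is None:
        n_octaves = 1
        while min(shape // (2**n_octaves)) >= 16:
            n_octaves += 1
    coarsest = shape // (2 ** (n_octaves - 1))
    if min(coarsest) < 8:
        axis = "xyz"[int(np.argmin(coarsest))]
        raise VolumeTooSmallError(
            f"volume too small along axis {axis}: coarsest octave would have "
            f"{min(coarsest)} voxels (< 8)"
        )

    s = levels_per_octave
    k = 2.0 ** (1.0 / s)
    base = volume.data.astype(np.float32)
    # Bring the input (assumed blur, voxel units) up to sigma0.
    sigma0_vox = sigma0_mm / h
    pre = np.sqrt(max(sigma0_vox**2 - assumed_blur_voxels**2, 1e-8))
    current = ndimage.gaussian_filter(base, pre, mode="nearest")

    octaves = []
    origin = volume.origin.copy()
    direction = volume.direction.copy()
    oct_spacing = np.full(3, h)
    oct_sigma0 = sigma0_mm
    for _o in range(n_octaves):
        gaussians = [current]
        sigmas = [oct_sigma0]
        for i in range(1, s + 3):
            sig_prev, sig_next = sigmas[-1], oct_sigma0 * k**i
            inc = np.sqrt(sig_next**2 - sig_prev**2) / oct_spacing[0]
            gaussians.append(ndimage.gaussian_filter(gaussians[-1], inc, mode="nearest"))
            sigmas.append(sig_next)
        dogs = [gaussians[i + 1] - gaussians[i] for i in range(s + 2)]
        octaves.append(
            Octave(gaussians, dogs, np.asarray(sigmas), oct_spacing.copy(), origin.copy(), direction)
        )
        # Seed the next octave from the level with sigma = 2*sigma0.
        current = gaussians[s][::2, ::2, ::2]
        oct_spacing = oct_spacing * 2
        oct_sigma0 = oct_sigma0 * 2
    return ScaleSpace(octaves, s, sigma0_mm)


def _local_extrema(stack: np.ndarray) -> np.ndarray:
    """Boolean mask of strict 80-neighbor extrema of a (L, nx, ny, nz) DoG stack,
    excluding the outer levels and spatial borders."""
    size = (3, 3, 3, 3)
    maxf = ndimage.maximum_filter(stack, size=size, mode="nearest")
    minf = ndimage.minimum_filter(stack, size=size, mode="nearest")
    is_ext = (stack == maxf) | (stack == minf)
    is_ext[0] = is_ext[-1] = False
    is_ext[:, [0, -1]] = False
    is_ext[:, :, [0, -1]] = False
    is_ext[:, :, :, [0, -1]] = False
    return is_ext


def detect_keypoints(
    pyramid: ScaleSpace,
    contrast_threshold: float = 0.02,
    edge_threshold: float = 10.0,
    max_features: int = 20000,
) -> FeatureSet:
    """Detect DoG extrema, refine to sub-voxel positions, filter, and return
    keypoints as a FeatureSet with empty descriptors.

    A candidate survives if the quadratically refined |DoG| response is at
    least ``contrast_threshold`` and the 3x3 spatial Hessian of the DoG is
    blob-like: all eigenvalues of one sign with
    max|lambda| / min|lambda| <= ``edge_threshold`` (edge/plate rejection).
    If more than ``max_features`` survive, the largest |response| are kept.
    """
    s = pyramid.levels_per_octave
    k = 2.0 ** (1.0 / s)
    pos_list, scale_list, resp_list, oct_list, lev_list = [], [], [], [], []

    for oi, octv in enumerate(pyramid.octaves):
        stack = np.stack(octv.dogs).astype(np.float32)  # (s+2, nx, ny, nz)
        mask = _local_extrema(stack)
        # Preliminary contrast gate before the expensive refinement.
        mask &= np.abs(stack) >= 0.5 * contrast_threshold
        ls, xs, ys, zs = np.nonzero(mask)
        if len(ls) == 0:
            continue

        D = stack
        c = D[ls, xs, ys, zs]
        # Spatial gradient and Hessian by central differences (voxel units).
        gx = 0.5 * (D[ls, xs + 1, ys, zs] - D[ls, xs - 1, ys, zs])
        gy = 0.5 * (D[ls, xs, ys + 1, zs] - D[ls, xs, ys - 1, zs])
        gz = 0.5 * (D[ls, xs, ys, zs + 1] - D[ls, xs, ys, zs - 1])
        hxx = D[ls, xs + 1, ys, zs] + D[ls, xs - 1, ys, zs] - 2 * c
        hyy = D[ls, xs, ys + 1, zs] + D[ls, xs, ys - 1, zs] - 2 * c
        hzz = D[ls, xs, ys, zs + 1] + D[ls, xs, ys, zs - 1] - 2 * c
        hxy = 0.25 * (
            D[ls, xs + 1, ys + 1, zs] - D[ls, xs + 1, ys - 1, zs]
            - D[ls, xs - 1, ys + 1, zs] + D[ls, xs - 1, ys - 1, zs]
        )
        hxz = 0.25 * (
            D[ls, xs + 1, ys, zs + 1] - D[ls, xs + 1, ys, zs - 1]
            - D[ls, xs - 1, ys, zs + 1] + D[ls, xs - 1, ys, zs - 1]
        )
        hyz = 0.25 * (
            D[ls, xs, ys + 1, zs + 1] - D[ls, xs, ys + 1, zs - 1]
            - D[ls, xs, ys - 1, zs + 1] + D[ls, xs, ys - 1, zs - 1]
        )
        H = np.empty((len(ls), 3, 3), dtype=np.float64)
        H[:, 0, 0], H[:, 1, 1], H[:, 2, 2] = hxx, hyy, hzz
        H[:, 0, 1] = H[:, 1, 0] = hxy
        H[:, 0, 2] = H[:, 2, 0] = hxz
        H[:, 1, 2] = H[:, 2, 1] = hyz
        g = np.stack([gx, gy, gz], axis=1).astype(np.float64)

        # Quadratic sub-voxel refinement: offset = -H^{-1} g (regularized
        # pseudo-inverse where H is near-singular; those fail the edge test
        # anyway).
        eigvals = np.linalg.eigvalsh(H)
        det = np.linalg.det(H)
        ok = np.abs(det) > 1e-20
        offset = np.zeros_like(g)
        if np.any(ok):
            offset[ok] = -np.linalg.solve(H[ok], g[ok, :, None])[..., 0]
        refined = c + 0.5 * np.einsum("ij,ij->i", g, offset)

        # Scale refinement: 1D quadratic along the level axis.
        dm = D[ls - 1, xs, ys, zs]
        dp = D[ls + 1, xs, ys, zs]
        denom = dm - 2 * c + dp
        dl = np.where(np.abs(denom) > 1e-12, 0.5 * (dm - dp) / np.where(denom == 0, 1, denom), 0.0)
        dl = np.clip(dl, -0.5, 0.5)

        keep = ok
        keep &= np.abs(refined) >= contrast_threshold
        keep &= np.all(np.abs(offset) <= 1.5, axis=1)
        # Edge/plate rejection on the spatial Hessian eigenvalues.
        lam_min = np.min(np.abs(eigvals), axis=1)
        lam_max = np.max(np.abs(eigvals), axis=1)
        same_sign = (eigvals > 0).all(axis=1) | (eigvals < 0).all(axis=1)
        keep &= same_sign & (lam_min > 0) & (lam_max <= edge_threshold * lam_min)
        if not np.any(keep):
            continue

        idx = np.stack([xs, ys, zs], axis=1)[keep] + np.clip(offset[keep], -1.0, 1.0)
        pos = octv.voxel_to_physical(idx)
        sig = octv.sigmas_mm[ls[keep]] * k ** dl[keep]
        pos_list.append(pos)
        scale_list.append(sig)
        resp_list.append(refined[keep])
        oct_list.append(np.full(keep.sum(), oi))
        lev_list.append(ls[keep])

    if not pos_list:
        return FeatureSet.empty()
    positions = np.concatenate(pos_list)
    scales = np.concatenate(scale_list)
    responses = np.concatenate(resp_list)
    octs = np.concatenate(oct_list)
    levs = np.concatenate(lev_list)

    # Drop duplicate (position, scale) tuples (within 1e-6), keeping the
    # strongest response; then cap at max_features by |response|.
    key = np.round(np.column_stack([positions, scales[:, None]]) / 1e-6).astype(np.int64)
    order = np.lexsort((-np.abs(responses),) + tuple(key.T[::-1]))
    key_sorted = key[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    sel = order[first]

    strength = np.abs(responses[sel])
    rank = np.lexsort(
        (positions[sel, 2], positions[sel, 1], positions[sel, 0], -strength)
    )
    sel = sel[rank][:max_features]
    n = len(sel)
    return FeatureSet(
        positions[sel], scales[sel], responses[sel],
        np.zeros((n, DESCRIPTOR_LENGTH)), octs[sel], levs[sel],
    )


_SAMPLES_PER_SUBREGION = 3  # sample lattice pitch = sigma (subregion width / 3)


def _descriptor_sampling(sigma_vox: float):
    """Precompute the fixed sampling lattice for one pyramid level.

    The descriptor window spans 4 subregions of width 3*sigma per axis;
    samples sit on a lattice with pitch sigma (the level is already
    Gaussian-smoothed at sigma, so finer sampling adds little).  Because
    the lattice is fixed relative to the bin grid, the trilinear spatial
    bin weights and the Gaussian radial weight are identical for every
    keypoint of the level and are folded together here once.

    Returns ``(offsets_vox (M, 3), corner_bins (M, 8), corner_weights (M, 8))``
    where corner bins index the flattened 4x4x4 spatial grid.
    """
    nb = DESCRIPTOR_SPATIAL_BINS
    w = 3.0 * sigma_vox  # subregion width, voxels
    n = nb * _SAMPLES_PER_SUBREGION
    # bin-coordinate positions in [0, nb), centered on the window
    u_axis = (np.arange(n) + 0.5) / _SAMPLES_PER_SUBREGION - 0.5
    ux, uy, uz = np.meshgrid(u_axis, u_axis, u_axis, indexing="ij")
    u = np.stack([ux, uy, uz], axis=-1).reshape(-1, 3)  # bin coords - 0.5 offset
    offsets = (u - (nb / 2.0 - 0.5)) * w  # voxel offsets from the keypoint

    r2 = np.sum(offsets**2, axis=1)
    gauss = np.exp(-r2 / (2.0 * (2.0 * w) ** 2))

    u0 = np.floor(u).astype(np.int64)
    fu = u - u0
    corner_bins = np.zeros((len(u), 8), dtype=np.int64)
    corner_w = np.zeros((len(u), 8))
    for corner in range(8):
        cx, cy, cz = (corner >> 2) & 1, (corner >> 1) & 1, corner & 1
        bx, by, bz = u0[:, 0] + cx, u0[:, 1] + cy, u0[:, 2] + cz
        valid = (bx >= 0) & (bx < nb) & (by >= 0) & (by < nb) & (bz >= 0) & (bz < nb)
        wx = fu[:, 0] if cx else 1 - fu[:, 0]
        wy = fu[:, 1] if cy else 1 - fu[:, 1]
        wz = fu[:, 2] if cz else 1 - fu[:, 2]
        corner_bins[:, corner] = (np.clip(bx, 0, nb - 1) * nb + np.clip(by, 0, nb - 1)) * nb + np.clip(bz, 0, nb - 1)
        corner_w[:, corner] = gauss * wx * wy * wz * valid
    return offsets, corner_bins, corner_w


def compute_descriptors(pyramid: ScaleSpace, keypoints: FeatureSet) -> FeatureSet:
    """Compute a 768-length gradient-histogram descriptor per keypoint.

    Gradients of the Gaussian level nearest each keypoint's scale are
    accumulated over a window of 4x4x4 spatial subregions, each 3*sigma
    voxels wide, with trilinear spatial weighting, Gaussian radial
    weighting, and hard assignment to the nearest of 12 solid-angle
    orientation bins.  Each histogram is normalized to unit norm, clipped
    at 0.2 per bin, and renormalized.  Keypoints whose window lies fully
    outside the grid are dropped (logged).
    """
    if len(keypoints) == 0:
        return FeatureSet.empty()
    descriptors = np.zeros((len(keypoints), DESCRIPTOR_LENGTH))
    keep_mask = np.ones(len(keypoints), dtype=bool)

    groups: dict[tuple[int, int], list[int]] = {}
    for i in range(len(keypoints)):
        oi = int(keypoints.octaves[i])
        octv = pyramid.octaves[oi]
        li = int(np.argmin(np.abs(octv.sigmas_mm - keypoints.scales[i])))
        groups.setdefault((oi, li), []).append(i)

    for (oi, li), members in sorted(groups.items()):
        octv = pyramid.octaves[oi]
        G = octv.gaussians[li].astype(np.float64)
        gx, gy, gz = np.gradient(G)  # voxel units
        shape = np.asarray(gx.shape)
        sigma_vox = octv.sigmas_mm[li] / octv.spacing[0]
        offsets, corner_bins, corner_w = _descriptor_sampling(sigma_vox)
        members = np.asarray(members)
        # voxel-space centers of this group's keypoints
        centers = ((keypoints.positions[members] - octv.origin) @ octv.direction) / octv.spacing

        m = len(offsets)
        chunk = max(1, int(6e6 // m))
        for start in range(0, len(members), chunk):
            mb = members[start : start + chunk]
            cb = centers[start : start + chunk]  # (B, 3)
            nk = len(mb)
            vox = np.round(cb[:, None, :] + offsets[None, :, :]).astype(int)  # (B, M, 3)
            inb = np.all((vox >= 0) & (vox < shape), axis=2)
            vc = np.clip(vox, 0, shape - 1)
            gvec = np.stack(
                [gx[vc[..., 0], vc[..., 1], vc[..., 2]],
                 gy[vc[..., 0], vc[..., 1], vc[..., 2]],
                 gz[vc[..., 0], vc[..., 1], vc[..., 2]]],
                axis=-1,
            )  # (B, M, 3)
            mag = np.sqrt(np.einsum("bmi,bmi->bm", gvec, gvec)) * inb
            obin = np.argmax(gvec @ _ORIENT_DIRS.T, axis=-1)  # (B, M)
            # scatter: flat index (keypoint, spatial bin, orientation bin)
            rows = np.arange(nk)[:, None, None]
            idx = (rows * DESCRIPTOR_LENGTH
                   + corner_bins[None, :, :] * DESCRIPTOR_ORIENT_BINS
                   + obin[:, :, None])
            wgt = mag[:, :, None] * corner_w[None, :, :]
            flat = np.bincount(idx.ravel(), weights=wgt.ravel(),
                               minlength=nk * DESCRIPTOR_LENGTH)
            descriptors[mb] = flat.reshape(nk, DESCRIPTOR_LENGTH)
            # fully-outside windows -> drop
            dead = ~inb.any(axis=1)
            if np.any(dead):
                keep_mask[mb[dead]] = False

    dropped = int((~keep_mask).sum())
    if dropped:
        logger.info("dropped %d keypoints with windows outside the grid", dropped)

    norms = np.linalg.norm(descriptors, axis=1)
    nz = norms > 0
    descriptors[nz] /= norms[nz, None]
    descriptors = np.minimum(descriptors, _DESCRIPTOR_CLIP)
    norms = np.linalg.norm(descriptors, axis=1)
    nz = norms > 0
    descriptors[nz] /= norms[nz, None]

    out = FeatureSet(
        keypoints.positions.copy(), keypoints.scales.copy(), keypoints.responses.copy(),
        descriptors, keypoints.octaves.copy(), keypoints.levels.copy(),
    )
    return out.subset(np.nonzero(keep_mask)[0])


def extract_features(
    volume: Volume,
    working_spacing: float = 2.0,
    sigma0_voxels: float = 1.6,
    levels_per_octave: int = 3,
    contrast_threshold: float = 0.02,
    edge_threshold: float = 10.0,
    max_features: int = 20000,
    lower_percentile: float = 1.0,
    upper_percentile: float = 99.0,
) -> FeatureSet:
    """Normalize, resample to an isotropic working grid, and detect + describe.

    Convenience wrapper used by the registration pipeline; positions come
    back in the volume's original physical space, so the working resolution
    only affects which features are found, not the coordinate frame.
    """
    norm = normalize_intensities(volume, lower_percentile, upper_percentile)
    iso = resample_isotropic(norm, working_spacing)
    pyr = build_scale_space(
        iso,
        levels_per_octave=levels_per_octave,
        sigma0_mm=sigma0_voxels * working_spacing,
    )
    kps = detect_keypoints(pyr, contrast_threshold, edge_threshold, max_features)
    return compute_descriptors(pyr, kps)
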