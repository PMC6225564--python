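"""Putative correspondences between two feature sets.

Stage 1 is global mutual nearest-neighbor matching on descriptor Euclidean
distance: a pair is kept only if each feature is the other's closest
descriptor in both directions.  Stage 2 restricts the search geometrically:
CT features outside the transformed CBCT field of view (plus a margin) are
pruned, and each feature is matched only against features within a fixed
physical radius of its transformed location.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .sift3d import FeatureSet
from .transforms import AffineTransform3D, invert_affine
from .volume_io import Volume

__all__ = ["MatchSet", "mutual_match", "prune_to_fov", "local_match"]


class MatchSet:
    """One-to-one index pairs between two FeatureSets with descriptor distances,
    sorted by ascending distance (ties broken by index)."""

    def __init__(self, pairs, distances):
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        distances = np.asarray(distances, dtype=float).reshape(-1)
        if len(pairs) != len(distances):
            raise ValueError("pairs and distances must be index-aligned")
        if len(pairs):
            if np.any(distances < 0):
                raise ValueError("descriptor distances must be >= 0")
            for col in (0, 1):
                if len(np.unique(pairs[:, col])) != len(pairs):
                    raise ValueError("matching must be one-to-one")
        order = np.lexsort((pairs[:, 1], pairs[:, 0], distances))
        self.pairs = pairs[order]
        self.distances = distances[order]

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls) -> "MatchSet":
        return cls(np.zeros((0, 2), dtype=int), np.zeros(0))

    def to_csv(self, path) -> None:
        table = np.column_stack([self.pairs, self.distances])
        np.savetxt(path, table, delimiter=",", header="idx_a,idx_b,distance",
                   comments="", fmt=("%d", "%d", "%.17g"))

    @classmethod
    def from_csv(cls, path) -> "MatchSet":
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if table.size == 0:
            return cls.empty()
        return cls(table[:, :2].astype(int), table[:, 2])


def _nn_blocked(da: np.ndarray, db: np.ndarray, block: int = 512):
    """Nearest neighbor in ``db`` for every row of ``da`` by blocked
    squared-Euclidean distance (BLAS matmul); ties go to the lower index."""
    na = len(da)
    nn = np.zeros(na, dtype=int)
    nd = np.zeros(na)
    b2 = np.einsum("ij,ij->i", db, db)
    for start in range(0, na, block):
        a = da[start : start + block]
        d2 = np.einsum("ij,ij->i", a, a)[:, None] + b2[None, :] - 2.0 * (a @ db.T)
        np.maximum(d2, 0.0, out=d2)
        j = np.argmin(d2, axis=1)
        nn[start : start + block] = j
        nd[start : start + block] = np.sqrt(d2[np.arange(len(a)), j])
    return nn, nd


def mutual_match(features_a: FeatureSet, features_b: FeatureSet) -> MatchSet:
    """Global mutual nearest-neighbor matching on descriptor distance.

    Pair (i, j) is kept iff j is i's nearest descriptor in B *and* i is j's
    nearest descriptor in A.  Nearest-neighbor ties are broken by the lower
    index, making the result deterministic.
    """
    if len(features_a) == 0 or len(features_b) == 0:
        return MatchSet.empty()
    da = np.asarray(features_a.descriptors, dtype=np.float64)
    db = np.asarray(features_b.descriptors, dtype=np.float64)
    ab, _ = _nn_blocked(da, db)
    ba, _ = _nn_blocked(db, da)
    ia = np.arange(len(da))
    keep = ba[ab] == ia
    # exact distances for the kept pairs (the blocked Gram trick loses a few
    # digits, which matters for the all-zero self-matching case)
    dist = np.linalg.norm(da[keep] - db[ab[keep]], axis=1)
    return MatchSet(np.column_stack([ia[keep], ab[keep]]), dist)


def prune_to_fov(
    features_ct: FeatureSet,
    cbct: Volume,
    transform: AffineTransform3D,
    margin: float = 10.0,
):
    """Keep CT features whose inverse-transformed position lies within the
    CBCT grid's physical box dilated by ``margin`` mm.

    ``transform`` maps CBCT physical space to CT physical space (the stage-1
    affine); CT features are pulled back through its inverse.  The test is
    done in CBCT index space so oblique direction matrices are handled
    exactly.  ``margin=np.inf`` keeps everything.  Returns the pruned
    FeatureSet and the indices it kept (into ``features_ct``).
    """
    if len(features_ct) == 0:
        return features_ct.subset(np.arange(0)), np.arange(0)
    if np.isinf(margin):
        idx = np.arange(len(features_ct))
        return features_ct.subset(idx), idx
    inv = invert_affine(transform)
    pos_cbct = inv.transform_points(features_ct.positions)
    idx_space = cbct.physical_to_voxel(pos_cbct)
    margin_vox = margin / cbct.spacing
    shape = np.asarray(cbct.shape)
    # The grid's physical box spans voxel centers +- half a voxel.
    lo = -0.5 - margin_vox
    hi = shape - 0.5 + margin_vox
    inside = np.all((idx_space >= lo) & (idx_space <= hi), axis=1)
    kept = np.nonzero(inside)[0]
    return features_ct.subset(kept), kept


def local_match(
    features_a: FeatureSet,
    features_b: FeatureSet,
    transform: AffineTransform3D,
    radius: float,
) -> MatchSet:
    """Transform-guided mutual matching within a physical search radius.

    Each feature of A (CBCT) is compared only against B (CT) features lying
    within ``radius`` mm of its transformed position, and symmetrically for
    B through the inverse transform; mutual nearest-neighbor consistency is
    then required.  With ``radius=np.inf`` this reduces to
    :func:`mutual_match`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive (mm)")
    if len(features_a) == 0 or len(features_b) == 0:
        return MatchSet.empty()
    if np.isinf(radius):
        return mutual_match(features_a, features_b)

    da = np.asarray(features_a.descriptors, dtype=np.float64)
    db = np.asarray(features_b.descriptors, dtype=np.float64)
    ta = transform.transform_points(features_a.positions)
    tb = invert_affine(transform).transform_points(features_b.positions)
    tree_b = cKDTree(features_b.positions)
    tree_a = cKDTree(features_a.positions)
    cand_b = tree_b.query_ball_point(ta, radius)
    cand_a = tree_a.query_ball_point(tb, radius)

    def restricted_nn(dsrc, ddst, candidates):
        nn = np.full(len(dsrc), -1, dtype=int)
        nd = np.full(len(dsrc), np.inf)
        for i, cand in enumerate(candidates):
            if not cand:
                continue
            cand = np.sort(np.asarray(cand))
            diff = ddst[cand] - dsrc[i]
            d2 = np.einsum("ij,ij->i", diff, diff)
            j = int(np.argmin(d2))
            nn[i] = cand[j]
            nd[i] = np.sqrt(max(d2[j], 0.0))
        return nn, nd

    ab, dist_ab = restricted_nn(da, db, cand_b)
    ba, _ = restricted_nn(db, da, cand_a)
    pairs, dists = [], []
    for i in range(len(da)):
        j = ab[i]
        if j >= 0 and ba[j] == i:
            pairs.append((i, j))
            dists.append(dist_ab[i])
    if not pairs:
        return MatchSet.empty()
    return MatchSet(np.asarray(pairs), np.asarray(dists))
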