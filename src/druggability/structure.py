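"""Structure representations built from CA traces.

Two constructors are provided, matching the structure arm of the
sequence-vs-structure comparison:

* a binary **contact map** — entry (i, j) is 1 iff the CA–CA Euclidean
  distance is strictly below a threshold (default 7 Å); the diagonal is 1,
  which makes the identity matrix the degenerate no-contact case;
* a fixed-size **point cloud** — CA coordinates centralized to the origin,
  subsampled uniformly without replacement (residue order preserved) when
  longer than ``n_points`` (default 400) and zero-padded when shorter, with
  uniform random rotations available as training-time augmentation
  (default multiplicity 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation


@dataclass
class ContactMap:
    protein_id: str
    matrix: np.ndarray
    threshold: float = 7.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)


@dataclass
class PointCloud:
    protein_id: str
    points: np.ndarray  # (n_points, 3), Å
    pad_mask: np.ndarray  # (n_points,), 1 = real residue, 0 = zero pad

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.pad_mask = np.asarray(self.pad_mask, dtype=np.uint8).ravel()
        if self.points.shape[0] != self.pad_mask.size:
            raise ValueError("pad_mask length must match number of points")

    @property
    def real_points(self) -> np.ndarray:
        return self.points[self.pad_mask == 1]


def contact_map(
    coords: Sequence | np.ndarray, threshold: float = 7.0, protein_id: str = ""
) -> ContactMap:
    """Binary CA–CA adjacency: 1 iff distance < threshold; diagonal 1."""
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.shape[0] < 1:
        raise ValueError("need at least one coordinate")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite coordinate")
    n = xyz.shape[0]
    if n == 1:
        mat = np.ones((1, 1), dtype=np.uint8)
    else:
        mat = (squareform(pdist(xyz)) < threshold).astype(np.uint8)
        np.fill_diagonal(mat, 1)
    return ContactMap(protein_id=protein_id, matrix=mat, threshold=threshold)


def build_point_cloud(
    coords: Sequence | np.ndarray,
    n_points: int = 400,
    rng_seed: int = 0,
    protein_id: str = "",
) -> PointCloud:
    """Centralized fixed-size point cloud with seeded subsampling.

    Coordinates are centered on their centroid; when more than ``n_points``
    residues are present a uniform subset is drawn without replacement
    (residue order preserved) and re-centralized so the centroid invariant
    holds for the retained points; shorter proteins are zero-padded.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.shape[0] < 1:
        raise ValueError("need at least one coordinate")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite coordinate")
    xyz = xyz - xyz.mean(axis=0)
    n = xyz.shape[0]
    if n > n_points:
        rng = np.random.default_rng(rng_seed)
        keep = np.sort(rng.choice(n, size=n_points, replace=False))
        xyz = xyz[keep]
        xyz = xyz - xyz.mean(axis=0)  # re-centralize the retained subset
        mask = np.ones(n_points, dtype=np.uint8)
    else:
        pad = np.zeros((n_points - n, 3))
        mask = np.concatenate([np.ones(n, dtype=np.uint8), np.zeros(n_points - n, dtype=np.uint8)])
        xyz = np.vstack([xyz, pad])
    return PointCloud(protein_id=protein_id, points=xyz, pad_mask=mask)


def rotation_matrix(rng_seed: int) -> np.ndarray:
    """A rotation drawn uniformly from SO(3) (unit-quaternion method)."""
    rng = np.random.default_rng(rng_seed)
    return Rotation.random(random_state=rng).as_matrix()


def random_rotation(cloud: PointCloud, rng_seed: int = 0) -> PointCloud:
    """Apply one uniform random rotation to all real points.

    Rotations fix the origin, so zero pads stay at (0, 0, 0) and the
    centroid of the real points remains the origin.
    """
    R = rotation_matrix(rng_seed)
    points = cloud.points @ R.T
    points[cloud.pad_mask == 0] = 0.0  # exact zeros for pads
    return PointCloud(
        protein_id=cloud.protein_id, points=points, pad_mask=cloud.pad_mask.copy()
    )


def augment_rotations(
    cloud: PointCloud, multiplicity: int = 3, rng_seed: int = 0
) -> list[PointCloud]:
    """Training-time augmentation: ``multiplicity`` rotated copies."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(multiplicity)
    return [random_rotation(cloud, rng_seed=int(s)) for s in seeds]
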