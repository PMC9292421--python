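"""Coaxial two-ring docking: axis detection, pose enumeration, scoring.

Two ring-shaped oligomers are aligned on a common axis (the minor axis of
each ring's gyration tensor), then ring B is pushed toward ring A along the
axis in fixed translation steps and rotated about the axis in fixed angle
steps, saving every distinct arrangement.  The rotation interval is reduced
by ring B's cyclic symmetry order so equivalent arrangements are enumerated
once.  Poses failing a steric clash rule are discarded before scoring;
surviving poses are ranked by the cross-ring interface pseudo-energy
(most favorable first).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.spatial import cKDTree

from .contacts import compute_pair_areas
from .errors import AmbiguousAxisError, GeometryError
from .structures import Structure
from .voromqa import Potential, atom_type

logger = logging.getLogger(__name__)

__all__ = ["Pose", "ring_axis", "enumerate_poses", "score_poses", "pose_structure"]


@dataclasses.dataclass
class Pose:
    """One coaxial arrangement of ring B relative to ring A.

    ``axial_offset`` is the z-translation of ring B's center above ring A's;
    ``rotation`` the angle about the common axis in [0, 360/symmetry_order).
    ``score`` is filled by :func:`score_poses` (interface pseudo-energy).
    """

    axial_offset: float
    rotation: float
    clash_fraction: float
    score: float | None = None


def ring_axis(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Unit symmetry axis and centroid of a ring-shaped structure.

    The axis is the gyration-tensor eigenvector with the smallest eigenvalue
    (rings are flat, so the normal is the thin direction), with its sign fixed
    toward +z.  Near-isotropic structures have no well-defined ring plane and
    raise :class:`AmbiguousAxisError`.
    """
    coords = s.coords()
    center = coords.mean(axis=0)
    centered = coords - center
    gyration = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(gyration)
    if evals[0] > 0.5 * evals[1]:
        raise AmbiguousAxisError(
            f"gyration spectrum too isotropic for a ring plane: {evals}"
        )
    axis = evecs[:, 0]
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis, center


def _align_to_z(s: Structure) -> Structure:
    """Rotate/translate a ring so its axis is +z and its centroid the origin."""
    axis, center = ring_axis(s)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + k + k @ k / (1.0 + c)
    return s.transformed(rot, np.zeros(3)).transformed(np.eye(3), -rot @ center)


def _rot_z(angle_deg: float) -> np.ndarray:
    c, sn = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])


def _clash_fraction(
    coords_a: np.ndarray, radii_a: np.ndarray, coords_b: np.ndarray, radii_b: np.ndarray
) -> float:
    """Fraction of cross-ring atom pairs closer than 0.6 x (sum of radii)."""
    cutoff = 0.6 * (radii_a.max() + radii_b.max())
    tree_a = cKDTree(coords_a)
    clashes = 0
    for jb, neighbors in enumerate(cKDTree(coords_b).query_ball_tree(tree_a, cutoff)):
        for ia in neighbors:
            d = np.linalg.norm(coords_b[jb] - coords_a[ia])
            if d < 0.6 * (radii_a[ia] + radii_b[jb]):
                clashes += 1
    return clashes / (len(coords_a) * len(coords_b))


def enumerate_poses(
    ring_a: Structure,
    ring_b: Structure,
    trans_step: float = 1.0,
    rot_step: float = 2.0,
    symmetry_order: int | None = None,
    max_clash_fraction: float = 0.001,
    probe: float = 1.4,
    max_offsets: int = 50,
) -> tuple[list[Pose], Structure, Structure]:
    """Enumerate the coaxial pose grid.

    Both rings are aligned to the z-axis; ring B starts at the largest axial
    offset where any cross-ring atom pair is within contact range
    (``r_i + r_j + 2*probe``, evaluated at rotation 0) and is pushed inward in
    ``trans_step`` decrements while at least one rotation at that offset
    passes the clash rule.  Rotations cover [0, 360/symmetry_order) in
    ``rot_step`` increments (symmetry order defaults to ring B's chain
    count).  Returns the pose grid plus the two aligned rings, so every pose
    is reproducible as a rigid transform of the aligned ring B.
    """
    aligned_a = _align_to_z(ring_a)
    aligned_b = _align_to_z(ring_b)
    if symmetry_order is None:
        symmetry_order = aligned_b.n_chains
    if symmetry_order < 1:
        raise GeometryError("symmetry order must be >= 1")
    ca, ra = aligned_a.coords(), aligned_a.radii()
    cb, rb = aligned_b.coords(), aligned_b.radii()

    # first-contact separation at rotation 0: largest offset with any pair in range
    t_first = -math.inf
    rmax_a, rmax_b = float(ra.max()), float(rb.max())
    pair_cut = rmax_a + rmax_b + 2.0 * probe
    tree_a = cKDTree(ca[:, :2])
    for jb, neighbors in enumerate(cKDTree(cb[:, :2]).query_ball_tree(tree_a, pair_cut)):
        for ia in neighbors:
            cut = ra[ia] + rb[jb] + 2.0 * probe
            dxy2 = float(np.sum((cb[jb, :2] - ca[ia, :2]) ** 2))
            if dxy2 < cut * cut:
                reach = math.sqrt(cut * cut - dxy2)
                t_first = max(t_first, ca[ia, 2] - cb[jb, 2] + reach)
    if not math.isfinite(t_first):
        logger.warning("rings never reach contact range on a common axis")
        return [], aligned_a, aligned_b

    angles = np.arange(0.0, 360.0 / symmetry_order - 1e-9, rot_step)
    poses: list[Pose] = []
    offset = t_first
    for _ in range(max_offsets):
        level: list[Pose] = []
        for angle in angles:
            moved = cb @ _rot_z(angle).T + np.array([0.0, 0.0, offset])
            cf = _clash_fraction(ca, ra, moved, rb)
            level.append(Pose(axial_offset=float(offset), rotation=float(angle), clash_fraction=cf))
        if min(p.clash_fraction for p in level) > max_clash_fraction:
            break
        poses.extend(level)
        offset -= trans_step
    return poses, aligned_a, aligned_b


def pose_structure(pose: Pose, aligned_a: Structure, aligned_b: Structure) -> Structure:
    """Materialize a pose as a combined structure (ring B chains lower-cased)."""
    moved = aligned_b.transformed(_rot_z(pose.rotation), np.array([0.0, 0.0, pose.axial_offset]))
    used = set(aligned_a.chain_ids)
    rename = {}
    for c in moved.chain_ids:
        new = c.lower() if c.lower() not in used else c + "'"
        rename[c] = new
        used.add(new)
    moved = moved.renamed_chains(rename)
    return Structure([a.copy() for a in aligned_a.atoms] + [a.copy() for a in moved.atoms])


def score_poses(
    poses: list[Pose],
    p: Potential,
    aligned_a: Structure,
    aligned_b: Structure,
    max_clash_fraction: float = 0.001,
    probe: float = 1.4,
    n_samples: int = 192,
    seed: int = 0,
) -> list[Pose]:
    """Score clash-passing poses by cross-ring interface energy and rank them.

    Most favorable (lowest) energy first; poses with no cross-ring contacts
    score 0 and are ranked last among the scored.
    """
    ca, ra = aligned_a.coords(), aligned_a.radii()
    cb, rb = aligned_b.coords(), aligned_b.radii()
    types_a = [atom_type(a) for a in aligned_a.atoms]
    types_b = [atom_type(a) for a in aligned_b.atoms]
    scored: list[Pose] = []
    for pose in poses:
        if pose.clash_fraction > max_clash_fraction:
            continue
        moved = cb @ _rot_z(pose.rotation).T + np.array([0.0, 0.0, pose.axial_offset])
        areas = compute_pair_areas(ca, ra, moved, rb, probe=probe, n_samples=n_samples, seed=seed)
        energy = sum(
            area * p.get(types_a[ia], types_b[jb]) for (ia, jb), area in areas.items()
        )
        pose.score = float(energy) if areas else 0.0
        scored.append(pose)
    scored.sort(
        key=lambda q: (0 if q.score != 0.0 else 1, q.score, q.axial_offset, q.rotation)
    )
    return scored
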