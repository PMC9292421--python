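"""Inter-atomic contact areas and solvent-exposed areas.

Contact areas follow the weighted-Voronoi (power diagram) construction: the
contact between two atoms is the face their power cells share, clipped to the
intersection of the two probe-expanded spheres, i.e. a subset of the radical
plane.  The face area is estimated by covering the radical-plane disc with a
deterministic low-discrepancy lattice and keeping the points whose power
distance to the pair is no larger than to any third atom.  For two isolated
equal spheres of radius r at distance d this reduces exactly to the analytic
bridge area pi*(r^2 - d^2/4).

Solvent areas are estimated on the probe-expanded sphere of each atom with a
Fibonacci lattice: a surface point is solvent-accessible when it lies inside
no other expanded sphere.  Both estimators are deterministic given the seed,
which only rotates/phases the lattices.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, GeometryError, MissingRadiusError
from .structures import Structure

__all__ = [
    "ContactMap",
    "ResidueContactMap",
    "compute_contact_map",
    "aggregate_residues",
    "interchain_subset",
    "write_contact_map",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

ResidueKey = tuple[str, int]


@dataclasses.dataclass
class ContactMap:
    """Sparse symmetric atom-atom contact areas plus per-atom solvent areas (A^2)."""

    atom_contacts: dict[tuple[int, int], float]  # (i, j) with i < j
    solvent_areas: np.ndarray  # per atom
    probe: float
    n_samples: int
    seed: int

    def get(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        key = (i, j) if i < j else (j, i)
        return self.atom_contacts.get(key, 0.0)

    def iter_contacts(self) -> Iterator[tuple[int, int, float]]:
        for (i, j), a in self.atom_contacts.items():
            yield i, j, a

    def total_contact_area(self) -> float:
        return float(sum(self.atom_contacts.values()))

    def per_atom_area(self) -> np.ndarray:
        """Half-share of each contact plus own solvent area, per atom."""
        out = np.array(self.solvent_areas, dtype=float)
        for (i, j), a in self.atom_contacts.items():
            out[i] += 0.5 * a
            out[j] += 0.5 * a
        return out


@dataclasses.dataclass
class ResidueContactMap:
    """Residue-level rollup of a :class:`ContactMap`.

    Keys are ``(chain_id, residue_index)``; pair keys are sorted tuples.
    A pair is inter-chain when its two chain ids differ.
    """

    contacts: dict[tuple[ResidueKey, ResidueKey], float]
    solvent: dict[ResidueKey, float]

    @staticmethod
    def pair_key(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: ResidueKey, b: ResidueKey) -> float:
        return self.contacts.get(self.pair_key(a, b), 0.0)

    def residues(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set(self.solvent)
        for a, b in self.contacts:
            out.add(a)
            out.add(b)
        return out

    def total_area(self) -> float:
        return float(sum(self.contacts.values()))

    @staticmethod
    def is_interchain(pair: tuple[ResidueKey, ResidueKey]) -> bool:
        return pair[0][0] != pair[1][0]

    def interchain_subset(self) -> "ResidueContactMap":
        return interchain_subset(self)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sunflower_disc(n: int, phase: float) -> np.ndarray:
    """Unit-disc lattice with near-uniform density (2D)."""
    k = np.arange(n)
    r = np.sqrt((k + 0.5) / n)
    th = k * _GOLDEN_ANGLE + phase
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _plane_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ux, uy, uz = float(u[0]), float(u[1]), float(u[2])
    if abs(ux) > 0.9:  # cross with the y axis instead of x
        e1 = (-uz, 0.0, ux)
    else:  # cross with the x axis
        e1 = (0.0, uz, -uy)
    n1 = math.sqrt(e1[0] ** 2 + e1[1] ** 2 + e1[2] ** 2)
    e1 = (e1[0] / n1, e1[1] / n1, e1[2] / n1)
    e2 = (
        uy * e1[2] - uz * e1[1],
        uz * e1[0] - ux * e1[2],
        ux * e1[1] - uy * e1[0],
    )
    return np.array(e1), np.array(e2)


def compute_contact_map(
    s: Structure, probe: float = 1.4, n_samples: int = 1024, seed: int = 0
) -> ContactMap:
    """Estimate power-diagram contact areas and solvent areas for ``s``.

    ``n_samples`` is the lattice size used both per contact disc and per
    solvent sphere; the estimator error shrinks roughly as 1/n_samples.
    Only pairs with center distance below ``r_i + r_j + 2*probe`` can touch.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    coords = s.coords()
    radii = s.radii()
    if not np.all(np.isfinite(coords)):
        raise GeometryError("non-finite coordinates")
    if np.any(radii <= 0):
        raise MissingRadiusError("all atoms need positive radii; run assign_radii first")
    n = len(radii)
    expanded = radii + probe
    rmax = float(expanded.max())
    tree = cKDTree(coords)

    rng = np.random.default_rng(seed)
    base_phase = rng.uniform(0.0, 2.0 * math.pi)
    # seeded random rotation applied to the sphere lattice
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    sphere_rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    sphere_lattice = _fibonacci_sphere(n_samples) @ sphere_rot.T

    # geometry of every candidate radical-plane disc, then one batched
    # neighbor query for the third-atom power tests
    cand: list[tuple[int, int, float, float, np.ndarray, np.ndarray]] = []
    for i, j in sorted(tree.query_pairs(2.0 * rmax)):
        d = float(np.linalg.norm(coords[j] - coords[i]))
        if d >= expanded[i] + expanded[j] or d < 1e-12:
            continue
        if d <= abs(expanded[i] - expanded[j]):
            # one expanded sphere engulfs the other: no radical-plane disc
            continue
        u = (coords[j] - coords[i]) / d
        h = (d * d + expanded[i] ** 2 - expanded[j] ** 2) / (2.0 * d)
        rho2 = expanded[i] ** 2 - h * h
        if rho2 <= 0:
            continue
        cand.append((i, j, math.sqrt(rho2), rho2, coords[i] + h * u, u))

    contacts: dict[tuple[int, int], float] = {}
    if cand:
        centers = np.array([c[4] for c in cand])
        neighbor_lists = tree.query_ball_point(centers, max(c[2] for c in cand) + rmax)
        for (i, j, rho, rho2, center, u), near in zip(cand, neighbor_lists):
            e1, e2 = _plane_basis(u)
            phase = base_phase + (97 * i + 31 * j) % 628 / 100.0
            disc = _sunflower_disc(n_samples, phase) * rho
            pts = center + disc[:, :1] * e1 + disc[:, 1:2] * e2
            # power of each sample w.r.t. the pair (equal for i and j on the plane)
            pair_power = np.einsum("ij,ij->i", disc, disc) - rho2
            near_arr = np.asarray(near, dtype=int)
            offsets = center - coords[near_arr]
            mask = (
                (near_arr != i)
                & (near_arr != j)
                & (np.einsum("ij,ij->i", offsets, offsets) < (rho + expanded[near_arr]) ** 2)
            )
            blockers = near_arr[mask]
            if len(blockers):
                diff = pts[None, :, :] - coords[blockers][:, None, :]
                power_k = (
                    np.einsum("kij,kij->ki", diff, diff) - expanded[blockers][:, None] ** 2
                )
                frac = float(np.all(power_k >= pair_power[None, :], axis=0).mean())
            else:
                frac = 1.0
            if frac > 0:
                contacts[(i, j)] = math.pi * rho2 * frac

    solvent = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere_lattice
        neighbors = [k for k in tree.query_ball_point(coords[i], expanded[i] + rmax) if k != i]
        if neighbors:
            diff = pts[None, :, :] - coords[neighbors][:, None, :]
            inside = np.einsum("kij,kij->ki", diff, diff) < expanded[neighbors][:, None] ** 2
            frac = float((~np.any(inside, axis=0)).mean())
        else:
            frac = 1.0
        solvent[i] = 4.0 * math.pi * expanded[i] ** 2 * frac

    return ContactMap(
        atom_contacts=contacts,
        solvent_areas=solvent,
        probe=probe,
        n_samples=n_samples,
        seed=seed,
    )


def compute_pair_areas(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
    probe: float = 1.4,
    n_samples: int = 256,
    seed: int = 0,
) -> dict[tuple[int, int], float]:
    """Contact areas restricted to cross-set atom pairs (A-side index, B-side index).

    Used where only an interface is needed (pose scoring): third-atom power
    tests still consider every atom of both sets, so the areas agree with the
    cross-set entries of :func:`compute_contact_map` on the combined structure.
    """
    coords = np.vstack([coords_a, coords_b])
    radii = np.concatenate([radii_a, radii_b])
    na = len(radii_a)
    expanded = radii + probe
    rmax = float(expanded.max())
    tree = cKDTree(coords)
    rng = np.random.default_rng(seed)
    base_phase = rng.uniform(0.0, 2.0 * math.pi)
    out: dict[tuple[int, int], float] = {}
    cross_tree = cKDTree(coords_b)
    for ia, neighbors in enumerate(cross_tree.query_ball_point(coords_a, 2.0 * rmax)):
        for jb in neighbors:
            j = na + jb
            d = float(np.linalg.norm(coords[j] - coords[ia]))
            if d >= expanded[ia] + expanded[j] or d < 1e-12:
                continue
            if d <= abs(expanded[ia] - expanded[j]):
                continue
            u = (coords[j] - coords[ia]) / d
            h = (d * d + expanded[ia] ** 2 - expanded[j] ** 2) / (2.0 * d)
            rho2 = expanded[ia] ** 2 - h * h
            if rho2 <= 0:
                continue
            rho = math.sqrt(rho2)
            center = coords[ia] + h * u
            e1, e2 = _plane_basis(u)
            phase = base_phase + (97 * ia + 31 * j) % 628 / 100.0
            disc = _sunflower_disc(n_samples, phase) * rho
            pts = center + disc[:, :1] * e1 + disc[:, 1:2] * e2
            pair_power = np.einsum("ij,ij->i", disc, disc) - rho2
            blockers = [
                k for k in tree.query_ball_point(center, rho + rmax) if k != ia and k != j
            ]
            if blockers:
                diff = pts[None, :, :] - coords[blockers][:, None, :]
                power_k = (
                    np.einsum("kij,kij->ki", diff, diff) - expanded[blockers][:, None] ** 2
                )
                frac = float(np.all(power_k >= pair_power[None, :], axis=0).mean())
            else:
                frac = 1.0
            if frac > 0:
                out[(ia, jb)] = math.pi * rho2 * frac
    return out


def aggregate_residues(cm: ContactMap, s: Structure) -> ResidueContactMap:
    """Roll atom-level areas up to residue level; intra-residue contacts excluded."""
    if len(cm.solvent_areas) != s.n_atoms:
        raise ConsistencyError("contact map does not match structure atom count")
    keys = [(a.chain_id, a.residue_index) for a in s.atoms]
    contacts: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for i, j, area in cm.iter_contacts():
        if i >= s.n_atoms or j >= s.n_atoms:
            raise ConsistencyError("atom index outside structure")
        ki, kj = keys[i], keys[j]
        if ki == kj:
            continue
        pk = ResidueContactMap.pair_key(ki, kj)
        contacts[pk] = contacts.get(pk, 0.0) + area
    solvent: dict[ResidueKey, float] = {}
    for i, a in enumerate(cm.solvent_areas):
        solvent[keys[i]] = solvent.get(keys[i], 0.0) + float(a)
    return ResidueContactMap(contacts=contacts, solvent=solvent)


def interchain_subset(rcm: ResidueContactMap) -> ResidueContactMap:
    """Keep only inter-chain residue pairs; solvent areas are dropped."""
    contacts = {
        pair: a for pair, a in rcm.contacts.items() if ResidueContactMap.is_interchain(pair)
    }
    return ResidueContactMap(contacts=contacts, solvent={})


def write_contact_map(cm: ContactMap, s: Structure, path) -> None:
    """Serialize as TSV: chain1 res1 atom1 chain2 res2 atom2 area (+ solvent rows)."""
    with open(path, "w") as fh:
        fh.write("# chain1\tres1\tatom1\tchain2\tres2\tatom2\tarea\n")
        for i, j, area in sorted(cm.iter_contacts()):
            a, b = s.atoms[i], s.atoms[j]
            fh.write(
                f"{a.chain_id}\t{a.residue_index}\t{a.atom_name}\t"
                f"{b.chain_id}\t{b.residue_index}\t{b.atom_name}\t{area:.4f}\n"
            )
        for i, a in enumerate(s.atoms):
            fh.write(
                f"{a.chain_id}\t{a.residue_index}\t{a.atom_name}\t"
                f"solvent\tsolvent\tsolvent\t{cm.solvent_areas[i]:.4f}\n"
            )
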