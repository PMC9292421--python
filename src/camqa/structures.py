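"""Structure data model, PDB input/output, radius assignment and synthetic fixtures.

The in-memory model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`Atom` records (chains -> residues -> atoms implied by the
``chain_id`` / ``residue_index`` fields).  Author residue numbering is the
correspondence key used throughout the package when comparing a model with a
target; no sequence alignment is ever performed.

The fixture generators (:func:`make_ring`, :func:`make_dimer`,
:func:`make_decoys`) build idealized helical assemblies and rigid-body decoy
ensembles with known ground-truth interface similarity, so every downstream
score can be exercised without external data.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    GeometryError,
    MissingRadiusError,
    NeedsMultimerError,
    ParseError,
)

__all__ = [
    "Atom",
    "Structure",
    "DecoySet",
    "DEFAULT_RADII",
    "read_structure",
    "write_structure",
    "assign_radii",
    "make_helix",
    "make_dimer",
    "make_ring",
    "make_two_ring_complex",
    "make_decoys",
    "make_decoy_ladder",
]

#: Van der Waals radii (angstrom) by element, plus a fallback default.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "default": 1.80,
}


@dataclasses.dataclass
class Atom:
    """One atom record with author numbering and an optional assigned radius."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), angstrom
    radius: float = 0.0

    def copy(self) -> "Atom":
        return dataclasses.replace(self, position=np.array(self.position, dtype=float))


class Structure:
    """An ordered collection of atoms; chain order is the order of first appearance."""

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise EmptyStructureError("structure must contain at least one atom")
        self.atoms: list[Atom] = list(atoms)

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain_id, residue_index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def chain_lengths(self) -> dict[str, int]:
        """Residues per chain."""
        counts: dict[str, set[int]] = {}
        for a in self.atoms:
            counts.setdefault(a.chain_id, set()).add(a.residue_index)
        return {c: len(s) for c, s in counts.items()}

    # -- transforms ---------------------------------------------------------

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        xyz = self.coords() @ rotation.T + translation
        for a, p in zip(out.atoms, xyz):
            a.position = p
        return out

    def subset_chains(self, chain_ids: Iterable[str]) -> "Structure":
        keep = set(chain_ids)
        atoms = [a.copy() for a in self.atoms if a.chain_id in keep]
        if not atoms:
            raise EmptyStructureError(f"no atoms left for chains {sorted(keep)}")
        return Structure(atoms)

    def renamed_chains(self, mapping: Mapping[str, str]) -> "Structure":
        out = self.copy()
        for a in out.atoms:
            a.chain_id = mapping.get(a.chain_id, a.chain_id)
        return out


@dataclasses.dataclass
class DecoySet:
    """A target plus perturbed decoys with known interface similarity.

    ``decoy_maps`` optionally carries the (ContactMap, ResidueContactMap)
    pair computed for each decoy while measuring its similarity, so callers
    scoring the same decoys need not recompute them.
    """

    target: Structure
    decoys: list[Structure]
    true_similarity: list[float]
    seed: int
    decoy_maps: list | None = None


# ---------------------------------------------------------------------------
# PDB input / output (gemmi-backed)
# ---------------------------------------------------------------------------


def read_structure(path, drop_hydrogens: bool = True, drop_hetero: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Chain order and author residue numbering are preserved.  Alternate
    locations are resolved to the highest-occupancy conformer (first seen on
    ties).  Hydrogen/deuterium atoms and HETATM residues are dropped by
    default.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if drop_hetero and residue.het_flag == "H":
                continue
            # altloc resolution: group by atom name, keep best occupancy
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                if drop_hydrogens and at.element.name in ("H", "D"):
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for name, at in best.items():
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms after filtering")
    return Structure(atoms)


def write_structure(s: Structure, path) -> None:
    """Write a structure as a PDB file (single model, occupancy 1.0)."""
    st = gemmi.Structure()
    st.name = "camqa"
    model = gemmi.Model("1")
    # gemmi's add_* methods copy their argument, so build bottom-up
    chain_order: list[str] = s.chain_ids
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        current_res: gemmi.Residue | None = None
        current_key: tuple[str, int] | None = None
        for a in s.atoms:
            if a.chain_id != cid:
                continue
            key = (a.chain_id, a.residue_index)
            if key != current_key:
                if current_res is not None:
                    chain.add_residue(current_res)
                current_res = gemmi.Residue()
                current_res.name = a.residue_name
                current_res.seqid = gemmi.SeqId(a.residue_index, " ")
                current_key = key
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*[float(x) for x in a.position])
            at.occ = 1.0
            at.b_iso = 0.0
            current_res.add_atom(at)
        if current_res is not None:
            chain.add_residue(current_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_radii(s: Structure, table: Mapping[str, float] | None = None) -> Structure:
    """Return a copy of ``s`` with radii assigned from ``table``.

    Lookup order: exact atom name, then element, then the ``"default"`` entry.
    """
    if table is None:
        table = DEFAULT_RADII
    out = s.copy()
    for a in out.atoms:
        r = table.get(a.atom_name)
        if r is None:
            r = table.get(a.element)
        if r is None:
            r = table.get("default")
        if r is None:
            raise MissingRadiusError(
                f"no radius for atom {a.atom_name} (element {a.element}) and no default"
            )
        a.radius = float(r)
    return out


# ---------------------------------------------------------------------------
# Idealized helical fixtures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # angstrom per residue along the helix axis
_HELIX_TWIST = 100.0  # degrees per residue
# (radius from axis, phase offset deg, axial offset, element) per backbone atom
_ATOM_GEOMETRY = {
    "N": (1.55, -26.0, -0.9, "N"),
    "CA": (2.30, 0.0, 0.0, "C"),
    "C": (1.70, 26.0, 0.9, "C"),
    "O": (2.05, 50.0, 1.2, "O"),
    "CB": (3.30, -5.0, 0.0, "C"),
}
# side-chain atoms beyond CB per non-ALA residue type
_SIDECHAIN_TIP = {
    "LEU": [
        ("CG", 4.40, -5.0, 0.0, "C"),
        ("CD1", 5.30, -20.0, -0.5, "C"),
        ("CD2", 5.30, 10.0, 0.5, "C"),
    ],
    "SER": [("OG", 4.20, -5.0, 0.0, "O")],
}

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _face_distance(a_deg: float, b_deg: float) -> float:
    d = abs((a_deg - b_deg) % 360.0)
    return min(d, 360.0 - d)


def make_helix(
    n_residues: int,
    chain_id: str = "A",
    seed: int = 0,
    jitter: float = 0.05,
    start_index: int = 1,
    hydro_face: float | None = None,
) -> Structure:
    """Idealized helix with its axis along x, centered at the origin.

    Backbone (N, CA, C, O) plus CB; rise 1.5 A/residue, twist 100 deg/residue.
    With ``hydro_face`` set (degrees; 0 points along +y, 90 along +z) the
    helix is amphipathic: residues whose side chain points within 60 degrees
    of the face are LEU (extra CG), those pointing away are SER (extra OG),
    the rest ALA.  This gives fixtures the compositional clustering (a
    hydrophobic face) that contact potentials detect in real proteins.
    ``seed`` controls a small deterministic coordinate jitter.
    """
    if n_residues < 1:
        raise GeometryError("helix needs at least one residue")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    mid = (n_residues - 1) / 2.0
    for i in range(n_residues):
        theta_deg = i * _HELIX_TWIST
        theta0 = math.radians(theta_deg)
        axial0 = (i - mid) * _HELIX_RISE
        if hydro_face is None:
            res_name = "ALA"
        else:
            dist = _face_distance(theta_deg - 5.0, hydro_face)  # CB phase is -5 deg
            res_name = "LEU" if dist <= 60.0 else ("ALA" if dist <= 110.0 else "SER")
        geometry = dict(_ATOM_GEOMETRY)
        for name, r, dphase, daxial, element in _SIDECHAIN_TIP.get(res_name, []):
            geometry[name] = (r, dphase, daxial, element)
        for name, (r, dphase, daxial, element) in geometry.items():
            th = theta0 + math.radians(dphase)
            pos = np.array(
                [axial0 + daxial, r * math.cos(th), r * math.sin(th)], dtype=float
            )
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, size=3)
            atoms.append(
                Atom(
                    chain_id=chain_id,
                    residue_index=start_index + i,
                    residue_name=res_name,
                    atom_name=name,
                    element=element,
                    position=pos,
                )
            )
    return assign_radii(Structure(atoms))


def make_dimer(
    len_a: int = 20,
    len_b: int | None = None,
    separation: float = 11.5,
    seed: int = 0,
    amphipathic: bool = True,
) -> Structure:
    """Two side-by-side helices forming an interface along y.

    With ``amphipathic`` (default) the two hydrophobic faces point at each
    other, so the native interface buries LEU side chains; with ``len_b``
    different from ``len_a`` the result is a hetero-dimer.
    """
    if len_b is None:
        len_b = len_a
    face_a = 0.0 if amphipathic else None
    face_b = 180.0 if amphipathic else None
    a = make_helix(len_a, "A", seed=seed, hydro_face=face_a)
    b = make_helix(len_b, "B", seed=seed + 1, hydro_face=face_b)
    b = b.transformed(np.eye(3), np.array([0.0, separation, 0.0]))
    return Structure(a.atoms + b.atoms)


def _rotation_z(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_ring(
    n_subunits: int,
    subunit_len: int,
    ring_radius: float,
    seed: int = 0,
    hydro_face: float | None = None,
) -> Structure:
    """Cn-symmetric ring of helical subunits lying in the xy-plane.

    Each subunit is one chain; the helix axes run tangentially so the
    assembly is flat and its symmetry axis is z.  Raises
    :class:`GeometryError` when the requested radius packs subunits on top of
    each other.
    """
    if n_subunits < 3:
        raise GeometryError("a ring needs at least 3 subunits")
    if n_subunits > len(_CHAIN_ALPHABET):
        raise GeometryError(f"at most {len(_CHAIN_ALPHABET)} subunits supported")
    # tangential extent of one subunit vs. available arc
    arc = 2.0 * math.pi * ring_radius / n_subunits
    if arc < 1.0:
        raise GeometryError("subunit centroids overlap: ring radius too small")
    template = make_helix(subunit_len, "A", seed=seed, hydro_face=hydro_face)
    # orient the helix axis tangentially (along y once placed at (R, 0, 0))
    template = template.transformed(_rotation_z(90.0), np.array([ring_radius, 0.0, 0.0]))
    chains: list[Atom] = []
    for k in range(n_subunits):
        rot = _rotation_z(360.0 * k / n_subunits)
        sub = template.transformed(rot, np.zeros(3))
        cid = _CHAIN_ALPHABET[k]
        for a in sub.atoms:
            a.chain_id = cid
        chains.extend(sub.atoms)
    ring = Structure(chains)
    # steric sanity: adjacent subunits must not interpenetrate
    first = ring.subset_chains([_CHAIN_ALPHABET[0]]).coords()
    second = ring.subset_chains([_CHAIN_ALPHABET[1]]).coords()
    from scipy.spatial import cKDTree

    dmin = cKDTree(first).query(second, k=1)[0].min()
    if dmin < 1.0:
        raise GeometryError(
            f"adjacent subunits overlap (min distance {dmin:.2f} A); increase ring_radius"
        )
    return ring


def make_two_ring_complex(
    n_subunits: int = 8,
    subunit_len: int = 12,
    ring_radius: float | None = None,
    stack_offset: float = 11.0,
    stack_rotation: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure, Structure]:
    """A coaxially stacked two-ring assembly plus its two component rings.

    Ring A carries its hydrophobic face on top (+z); ring B is the mirror
    image of ring A (z reflection), so the two stacking faces are exactly
    complementary and the assembly has a sharp packing optimum at
    ``stack_rotation`` 0.  Returns ``(complex, ring_a, ring_b)`` with ring B
    of the complex at ``stack_offset`` along +z, rotated by
    ``stack_rotation`` degrees about z and its chains renamed to lower-case.
    """
    if ring_radius is None:
        # tight packing: one subunit per arc segment plus ~3 A clearance
        ring_radius = (subunit_len * _HELIX_RISE + 3.0) * n_subunits / (2.0 * math.pi)
    ring_a = make_ring(n_subunits, subunit_len, ring_radius, seed=seed, hydro_face=90.0)
    ring_b = ring_a.transformed(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    ring_b = ring_b.renamed_chains({c: c.lower() for c in ring_b.chain_ids})
    moved = ring_b.transformed(_rotation_z(stack_rotation), np.array([0.0, 0.0, stack_offset]))
    combined = Structure([a.copy() for a in ring_a.atoms] + [a.copy() for a in moved.atoms])
    return combined, ring_a, ring_b


# ---------------------------------------------------------------------------
# Decoy generation
# ---------------------------------------------------------------------------


def make_decoy_ladder(
    target: Structure,
    n: int,
    max_shift: float,
    max_rot: float,
    noise_sigma: float,
    seed: int,
    probe: float = 1.4,
    n_samples: int = 256,
    contact_seed: int = 0,
) -> DecoySet:
    """Graded decoy ladder: perturbation bounds ramp linearly from 0 to max.

    Decoy i is generated with bounds ``(i/(n-1)) * (max_shift, max_rot)``, so
    the ensemble spans near-native to fully disrupted interfaces — the shape
    needed for rank-correlation experiments.
    """
    if n < 2:
        raise ValueError("a ladder needs at least 2 decoys")
    from .contacts import aggregate_residues, compute_contact_map

    target_rcm = aggregate_residues(
        compute_contact_map(target, probe=probe, n_samples=n_samples, seed=contact_seed),
        target,
    )
    decoys: list[Structure] = []
    sims: list[float] = []
    maps: list = []
    for i in range(n):
        frac = i / (n - 1)
        step = make_decoys(
            target,
            1,
            frac * max_shift,
            frac * max_rot,
            noise_sigma,
            seed=seed + i,
            probe=probe,
            n_samples=n_samples,
            contact_seed=contact_seed,
            target_rcm=target_rcm,
        )
        decoys.extend(step.decoys)
        sims.extend(step.true_similarity)
        maps.extend(step.decoy_maps or [])
    return DecoySet(
        target=target, decoys=decoys, true_similarity=sims, seed=seed, decoy_maps=maps
    )


def _random_rotation_matrix(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    if max_angle_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_angle_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def make_decoys(
    target: Structure,
    n: int,
    max_shift: float,
    max_rot: float,
    noise_sigma: float,
    seed: int,
    probe: float = 1.4,
    n_samples: int = 256,
    contact_seed: int = 0,
    target_rcm=None,
) -> DecoySet:
    """Rigid-body decoy ensemble with ground-truth interface CAD similarity.

    One chain (the last) of each decoy receives a rigid transform drawn
    uniformly up to ``(max_shift, max_rot)``; all atoms additionally receive
    i.i.d. Gaussian coordinate noise.  ``true_similarity`` is the interface
    CAD-score of each decoy against the unperturbed target, recomputed from
    contact maps with the same estimator settings.
    """
    if target.n_chains < 2:
        raise NeedsMultimerError("decoy generation needs a multimeric target")
    from .cad import cad_interface
    from .contacts import aggregate_residues, compute_contact_map

    if target_rcm is None:
        target_rcm = aggregate_residues(
            compute_contact_map(
                target, probe=probe, n_samples=n_samples, seed=contact_seed
            ),
            target,
        )
    moving = target.chain_ids[-1]
    rng = np.random.default_rng(seed)
    decoys: list[Structure] = []
    sims: list[float] = []
    maps: list = []
    for _ in range(n):
        d = target.copy()
        rot = _random_rotation_matrix(rng, max_rot)
        if max_shift > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = rng.uniform(0.0, max_shift) * direction
        else:
            shift = np.zeros(3)
        moving_idx = [i for i, a in enumerate(d.atoms) if a.chain_id == moving]
        centroid = np.mean([d.atoms[i].position for i in moving_idx], axis=0)
        for i in moving_idx:
            p = d.atoms[i].position
            d.atoms[i].position = rot @ (p - centroid) + centroid + shift
        if noise_sigma > 0:
            for a in d.atoms:
                a.position = a.position + rng.normal(0.0, noise_sigma, size=3)
        decoy_cm = compute_contact_map(
            d, probe=probe, n_samples=n_samples, seed=contact_seed
        )
        decoy_rcm = aggregate_residues(decoy_cm, d)
        sims.append(cad_interface(target_rcm, decoy_rcm))
        decoys.append(d)
        maps.append((decoy_cm, decoy_rcm))
    return DecoySet(
        target=target, decoys=decoys, true_similarity=sims, seed=seed, decoy_maps=maps
    )
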