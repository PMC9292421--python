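"""Contact-area estimator: analytic oracles, invariances, residue rollup."""

import math

import numpy as np
import pytest

from camqa.contacts import (
    ResidueContactMap,
    aggregate_residues,
    compute_contact_map,
    interchain_subset,
    write_contact_map,
)
from camqa.errors import GeometryError, MissingRadiusError
from camqa.structures import Atom, Structure, make_dimer


def ball(chain, resi, name, x, y, z, r, element="C"):
    return Atom(chain, resi, "ALA", name, element, np.array([x, y, z], float), r)


def brute_force_pair_area(centers, radii, i, j, n_points=200_000, rng_seed=12345):
    """Independent oracle: uniform random sampling of the radical-plane disc.

    Same geometric definition (power-diagram face clipped to the two balls),
    entirely different point scheme (pseudo-random instead of a lattice).
    """
    ci, cj = centers[i], centers[j]
    ri, rj = radii[i], radii[j]
    d = np.linalg.norm(cj - ci)
    if d >= ri + rj or d <= abs(ri - rj):
        return 0.0
    u = (cj - ci) / d
    h = (d * d + ri * ri - rj * rj) / (2 * d)
    rho2 = ri * ri - h * h
    if rho2 <= 0:
        return 0.0
    rho = math.sqrt(rho2)
    center = ci + h * u
    helper = np.array([0.0, 1.0, 0.0]) if abs(u[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    rng = np.random.default_rng(rng_seed)
    # rejection-sample uniform points in the disc
    xy = rng.uniform(-1, 1, size=(int(n_points * 1.5), 2))
    xy = xy[np.einsum("ij,ij->i", xy, xy) <= 1.0][:n_points] * rho
    pts = center + xy[:, :1] * e1 + xy[:, 1:2] * e2
    pair_power = np.einsum("ij,ij->i", xy, xy) - rho2
    keep = np.ones(len(pts), dtype=bool)
    for k in range(len(centers)):
        if k in (i, j):
            continue
        diff = pts - centers[k]
        keep &= np.einsum("ij,ij->i", diff, diff) - radii[k] ** 2 >= pair_power
    return math.pi * rho2 * keep.mean()


class TestTwoBallOracle:
    def test_equal_balls_bridge_area_is_analytic(self):
        """Two r=2 balls at d=2: power face = disc of area pi*(r^2-d^2/4)=3pi."""
        s = Structure(
            [ball("A", 1, "CA", 0, 0, 0, 2.0), ball("A", 2, "CA", 2, 0, 0, 2.0)]
        )
        cm = compute_contact_map(s, probe=0.0, n_samples=4096, seed=1)
        area = cm.get(0, 1)
        assert area == pytest.approx(3 * math.pi, rel=0.03)

    def test_isolated_ball_fully_solvated(self):
        s = Structure([ball("A", 1, "CA", 0, 0, 0, 1.7)])
        cm = compute_contact_map(s, probe=1.4, n_samples=1024, seed=0)
        assert not cm.atom_contacts
        assert cm.solvent_areas[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-6)

    def test_equilateral_triangle_symmetry(self):
        h = math.sqrt(3)
        s = Structure(
            [
                ball("A", 1, "CA", 0, 0, 0, 1.8),
                ball("A", 2, "CA", 2, 0, 0, 1.8),
                ball("A", 3, "CA", 1, h, 0, 1.8),
            ]
        )
        cm = compute_contact_map(s, probe=0.5, n_samples=2048, seed=0)
        a12, a13, a23 = cm.get(0, 1), cm.get(0, 2), cm.get(1, 2)
        assert a12 == pytest.approx(a13, rel=0.05)
        assert a12 == pytest.approx(a23, rel=0.05)


@pytest.fixture(scope="module")
def small_system():
    rng = np.random.default_rng(8)
    atoms = [
        ball("A", i + 1, "CA", *rng.uniform(0, 6, 3), rng.uniform(1.4, 2.0))
        for i in range(12)
    ]
    return Structure(atoms)


class TestEstimatorProperties:
    def test_agreement_with_brute_force_oracle(self, small_system):
        cm = compute_contact_map(small_system, probe=0.8, n_samples=2048, seed=3)
        centers = small_system.coords()
        radii = small_system.radii() + 0.8
        for (i, j), area in cm.atom_contacts.items():
            if area < 1.0:
                continue
            oracle = brute_force_pair_area(centers, radii, i, j)
            assert area == pytest.approx(oracle, rel=0.05)

    def test_convergence_in_sample_count(self, small_system):
        cm1 = compute_contact_map(small_system, probe=0.8, n_samples=512, seed=3)
        cm4 = compute_contact_map(small_system, probe=0.8, n_samples=2048, seed=3)
        for key in cm4.atom_contacts:
            a1, a4 = cm1.get(*key), cm4.get(*key)
            assert abs(a1 - a4) / max(a4, 1.0) < 0.05

    def test_scale_covariance(self, small_system):
        """Doubling coordinates, radii and probe multiplies areas by 4."""
        cm = compute_contact_map(small_system, probe=0.8, n_samples=1024, seed=3)
        doubled = small_system.copy()
        for a in doubled.atoms:
            a.position = a.position * 2.0
            a.radius = a.radius * 2.0
        cm2 = compute_contact_map(doubled, probe=1.6, n_samples=1024, seed=3)
        for key, area in cm.atom_contacts.items():
            if area < 0.5:
                continue
            assert cm2.get(*key) == pytest.approx(4.0 * area, rel=0.05)

    def test_rigid_motion_invariance(self, small_system):
        cm = compute_contact_map(small_system, probe=0.8, n_samples=1024, seed=3)
        ang = 0.7
        rot = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0],
                [math.sin(ang), math.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        moved = small_system.transformed(rot, np.array([5.0, -3.0, 2.0]))
        cm2 = compute_contact_map(moved, probe=0.8, n_samples=1024, seed=3)
        for key, area in cm.atom_contacts.items():
            if area < 0.5:
                continue
            assert cm2.get(*key) == pytest.approx(area, rel=0.05, abs=0.3)

    def test_per_atom_total_below_expanded_sphere_area(self, small_system):
        cm = compute_contact_map(small_system, probe=0.8, n_samples=1024, seed=3)
        totals = cm.per_atom_area() + cm.per_atom_area() * 0  # copy
        full = cm.solvent_areas * 0
        for i, a in enumerate(small_system.atoms):
            full[i] = 4 * math.pi * (a.radius + 0.8) ** 2
        # half-share accounting keeps contact+solvent within the sphere area
        per_atom = np.array(cm.solvent_areas, dtype=float)
        for (i, j), area in cm.atom_contacts.items():
            per_atom[i] += area
            per_atom[j] += area
        assert np.all(per_atom <= full * 1.05)

    def test_missing_radius_rejected(self):
        s = Structure([Atom("A", 1, "ALA", "CA", "C", np.zeros(3), 0.0)])
        with pytest.raises(MissingRadiusError):
            compute_contact_map(s, n_samples=128)

    def test_nonfinite_coordinates_rejected(self):
        s = Structure([ball("A", 1, "CA", np.nan, 0, 0, 1.7)])
        with pytest.raises(GeometryError):
            compute_contact_map(s, n_samples=128)


class TestResidueAggregation:
    def test_area_conservation(self, dimer, dimer_maps):
        cm, rcm = dimer_maps
        keys = [(a.chain_id, a.residue_index) for a in dimer.atoms]
        atom_total = sum(
            area for (i, j), area in cm.atom_contacts.items() if keys[i] != keys[j]
        )
        assert rcm.total_area() == pytest.approx(atom_total, abs=1e-6)
        assert sum(rcm.solvent.values()) == pytest.approx(cm.solvent_areas.sum(), abs=1e-6)

    def test_hand_built_rollup(self):
        s = Structure(
            [
                ball("A", 1, "CA", 0, 0, 0, 2.0),
                ball("A", 1, "CB", 1, 0, 0, 2.0),
                ball("A", 2, "CA", 0, 3, 0, 2.0),
                ball("A", 2, "CB", 1, 3, 0, 2.0),
            ]
        )
        from camqa.contacts import ContactMap

        cm = ContactMap(
            atom_contacts={(0, 2): 2.0, (1, 2): 3.0, (0, 1): 7.0},
            solvent_areas=np.zeros(4),
            probe=0.0,
            n_samples=64,
            seed=0,
        )
        rcm = aggregate_residues(cm, s)
        # intra-residue contact (0,1) excluded; (0,2)+(1,2) merge to one pair
        assert rcm.get(("A", 1), ("A", 2)) == pytest.approx(5.0)
        assert len(rcm.contacts) == 1

    def test_interchain_subset_counts_and_idempotence(self, dimer_maps):
        _, rcm = dimer_maps
        sub = interchain_subset(rcm)
        assert sub.contacts
        assert all(ResidueContactMap.is_interchain(p) for p in sub.contacts)
        assert not sub.solvent
        again = interchain_subset(sub)
        assert again.contacts == sub.contacts

    def test_monomer_has_empty_interchain_subset(self):
        from camqa.structures import make_helix

        h = make_helix(8, seed=0)
        cm = compute_contact_map(h, n_samples=128, seed=0)
        rcm = aggregate_residues(cm, h)
        assert interchain_subset(rcm).contacts == {}

    def test_serialization_includes_solvent_rows(self, dimer, dimer_maps, tmp_path):
        cm, _ = dimer_maps
        out = tmp_path / "contacts.tsv"
        write_contact_map(cm, dimer, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        solvent_rows = [l for l in lines if "solvent" in l]
        assert len(solvent_rows) == dimer.n_atoms
        assert len(lines) == len(cm.atom_contacts) + dimer.n_atoms
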