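"""Coulomb potential/field, bond-axis projections and counterion placement."""

import numpy as np
import pytest

import voxsite as vx
from voxsite.electrostatics import (BondAxis, ChargeSet, FieldVector,
                                    IonPlacementConfig, bond_projection,
                                    field_at, field_from_au, field_to_au,
                                    place_counterions, potential_at,
                                    potential_from_au, potential_to_au,
                                    COULOMB_KJ_MOL_ANG, _candidate_grid,
                                    _potential_many)


def naive_potential(positions, charges, r):
    """Independent double-loop oracle."""
    v = 0.0
    for p, q in zip(positions, charges):
        v += q / np.sqrt(sum((a - b) ** 2 for a, b in zip(r, p)))
    return COULOMB_KJ_MOL_ANG * v


def naive_field(positions, charges, r):
    e = np.zeros(3)
    for p, q in zip(positions, charges):
        d = np.asarray(r, dtype=float) - np.asarray(p, dtype=float)
        e += q * d / np.linalg.norm(d) ** 3
    return COULOMB_KJ_MOL_ANG * e


class TestPotentialAndField:
    def test_unit_charge_at_one_angstrom(self):
        cs = ChargeSet([[0, 0, 0]], [1.0])
        assert potential_at(cs, [1.0, 0, 0]) == pytest.approx(1389.35, abs=0.01)

    def test_midpoint_of_opposite_charges_is_zero(self):
        cs = ChargeSet([[1, 0, 0], [-1, 0, 0]], [1.0, -1.0])
        assert potential_at(cs, [0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_field_single_charge(self):
        cs = ChargeSet([[0, 0, 0]], [1.0])
        d = 2.0
        E = field_at(cs, [d, 0, 0]).E
        np.testing.assert_allclose(E, [COULOMB_KJ_MOL_ANG / d ** 2, 0, 0])

    def test_symmetric_pair_field_along_axis(self):
        cs = ChargeSet([[1, 0, 0], [-1, 0, 0]], [1.0, -1.0])
        E = field_at(cs, [0, 3.0, 0]).E  # perpendicular bisector
        assert abs(E[1]) < 1e-12 and abs(E[2]) < 1e-12
        assert E[0] < 0  # points from + to - along the pair axis

    def test_against_naive_double_loop(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(scale=4.0, size=(50, 3))
        q = rng.uniform(-1, 1, size=50)
        cs = ChargeSet(pos, q)
        r = np.array([9.0, -3.0, 5.0])
        assert potential_at(cs, r) == pytest.approx(
            naive_potential(pos, q, r), rel=1e-10)
        np.testing.assert_allclose(field_at(cs, r).E, naive_field(pos, q, r),
                                   rtol=1e-10)

    def test_field_is_negative_gradient_of_potential(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cs = ChargeSet(rng.normal(scale=3, size=(10, 3)),
                           rng.uniform(-1, 1, 10))
            r = rng.normal(scale=8, size=3) + np.array([12.0, 0, 0])
            h = 1e-5
            num = np.array([
                -(potential_at(cs, r + h * e) - potential_at(cs, r - h * e)) / (2 * h)
                for e in np.eye(3)])
            np.testing.assert_allclose(field_at(cs, r).E, num, rtol=1e-5)

    def test_superposition(self):
        rng = np.random.default_rng(8)
        a = ChargeSet(rng.normal(size=(5, 3)), rng.uniform(-1, 1, 5))
        b = ChargeSet(rng.normal(size=(7, 3)) + 4.0, rng.uniform(-1, 1, 7))
        r = np.array([10.0, 10.0, -10.0])
        assert potential_at(a + b, r) == pytest.approx(
            potential_at(a, r) + potential_at(b, r), rel=1e-12)
        np.testing.assert_allclose(field_at(a + b, r).E,
                                   field_at(a, r).E + field_at(b, r).E,
                                   rtol=1e-12)

    def test_coincident_point_rejected(self):
        cs = ChargeSet([[0, 0, 0]], [1.0])
        with pytest.raises(vx.VoxsiteError, match="coincides"):
            potential_at(cs, [0, 0, 0])

    def test_unit_round_trip(self):
        v = 280.3
        assert potential_from_au(potential_to_au(v)) == pytest.approx(v, rel=1e-12)
        e = np.array([1.5, -2.5, 0.25])
        np.testing.assert_allclose(field_from_au(field_to_au(e)), e, rtol=1e-12)

    def test_au_units_consistent(self):
        cs = ChargeSet([[0, 0, 0]], [1.0])
        v_kj = potential_at(cs, [1, 0, 0], units="kJ/mol")
        v_au = potential_at(cs, [1, 0, 0], units="au")
        assert v_au == pytest.approx(potential_to_au(v_kj), rel=1e-12)


class TestBondProjection:
    def test_zero_fields_zero_projections(self):
        axis = BondAxis([0, 0, 0], [1.5, 0, 0])
        p = bond_projection(FieldVector([0, 0, 0]), FieldVector([0, 0, 0]),
                            axis, 0.5, -0.5)
        assert (p.e_from, p.e_to, p.f_from, p.f_to, p.net_attraction) == \
               (0, 0, 0, 0, 0)

    def test_arithmetic_example(self):
        """E_C = u, E_N = u, q_C = +1, q_N = -1 -> F_C.u=1, F_N.u=-1, A=2."""
        axis = BondAxis([0, 0, 0], [2.0, 0, 0])
        u = axis.u
        p = bond_projection(FieldVector(u), FieldVector(u), axis, 1.0, -1.0)
        assert p.f_from == pytest.approx(1.0)
        assert p.f_to == pytest.approx(-1.0)
        assert p.net_attraction == pytest.approx(2.0)

    def test_matches_full_vector_computation(self):
        """Projection of q E onto u computed independently."""
        rng = np.random.default_rng(3)
        cs = ChargeSet(rng.normal(scale=5, size=(20, 3)) + 15.0,
                       rng.uniform(-0.8, 0.8, 20))
        c1, n4 = np.array([0.0, 0.0, 0.0]), np.array([1.3, 0.2, -0.1])
        q_c, q_n = 0.62, -0.53
        axis = BondAxis(c1, n4)
        p = bond_projection(field_at(cs, c1), field_at(cs, n4), axis, q_c, q_n)
        u = (n4 - c1) / np.linalg.norm(n4 - c1)
        f_c = q_c * naive_field(cs.positions, cs.charges, c1) @ u
        f_n = q_n * naive_field(cs.positions, cs.charges, n4) @ u
        assert p.net_attraction == pytest.approx(f_c - f_n, rel=1e-10)

    def test_unit_mismatch_rejected(self):
        axis = BondAxis([0, 0, 0], [1, 0, 0])
        with pytest.raises(vx.VoxsiteError, match="unit"):
            bond_projection(FieldVector([1, 0, 0], "kJ/mol"),
                            FieldVector([1, 0, 0], "au"), axis, 1, -1)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(vx.VoxsiteError, match="coincide"):
            BondAxis([1, 1, 1], [1, 1, 1])


SMALL_CFG = IonPlacementConfig(grid_spacing=0.5, min_solute_dist=2.0,
                               min_ion_dist=1.5, ion_charge=1.0, n_ions=3,
                               padding_extra=1.0)


class TestIonPlacement:
    def test_single_anion_ion_on_first_shell(self):
        s, _ = vx.generate_charged_system("point")  # one -1 e charge at origin
        cfg = IonPlacementConfig(n_ions=1)
        res = place_counterions(s, cfg)
        assert np.linalg.norm(res.positions[0]) == pytest.approx(
            cfg.min_solute_dist, abs=cfg.grid_spacing)
        assert res.final_net_charge == pytest.approx(0.0)

    def test_neutralize_counts_ions(self):
        atoms = [vx.Atom(serial=i + 1, name="C", element="C", res_name="CHG",
                         res_seq=i + 1, chain="A", xyz=(3.0 * i, 0.0, 0.0),
                         charge=-1.0) for i in range(3)]
        s = vx.Structure(id="minus3", atoms=atoms)
        res = place_counterions(s, IonPlacementConfig(n_ions="neutralize"))
        assert len(res.positions) == 3
        assert res.final_net_charge == pytest.approx(0.0)

    def test_distance_constraints_respected(self):
        s, _ = vx.generate_charged_system("random-cloud", n=5, seed=3)
        cs = ChargeSet.from_structure(s)
        res = place_counterions(cs, SMALL_CFG)
        pos = res.positions
        for p in pos:
            d = np.linalg.norm(cs.positions - p, axis=1)
            assert d.min() >= SMALL_CFG.min_solute_dist - 1e-9
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.linalg.norm(pos[i] - pos[j]) >= SMALL_CFG.min_ion_dist - 1e-9

    def test_greedy_step_is_grid_optimal(self):
        """At each placement the chosen point has the minimum potential over
        the admissible grid (verified by exhaustive recomputation)."""
        s, _ = vx.generate_charged_system("random-cloud", n=4, seed=7)
        cs = ChargeSet.from_structure(s)
        res = place_counterions(cs, SMALL_CFG)
        grid = _candidate_grid(cs, SMALL_CFG)
        placed = []
        for step, chosen in enumerate(res.positions):
            sources = cs
            if placed:
                sources = cs + ChargeSet(np.array(placed),
                                         np.full(len(placed), SMALL_CFG.ion_charge))
                admissible = np.ones(len(grid), dtype=bool)
                for p in placed:
                    admissible &= (np.linalg.norm(grid - p, axis=1)
                                   >= SMALL_CFG.min_ion_dist)
            else:
                admissible = np.ones(len(grid), dtype=bool)
            v = _potential_many(sources, grid[admissible])
            v_chosen = _potential_many(sources, chosen[None])[0]
            assert v_chosen <= v.min() + 1e-9
            placed.append(chosen)

    def test_exhausted_grid_reports_count(self):
        s, _ = vx.generate_charged_system("point")
        cfg = IonPlacementConfig(grid_spacing=0.5, min_solute_dist=2.0,
                                 min_ion_dist=8.0, n_ions=50, padding_extra=0.5)
        with pytest.raises(vx.VoxsiteError, match="placing"):
            place_counterions(s, cfg)

    def test_bad_config_rejected(self):
        with pytest.raises(vx.VoxsiteError):
            IonPlacementConfig(grid_spacing=6.0, min_ion_dist=5.0)
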