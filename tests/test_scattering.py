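"""Sphere-model coarse graining, hydration, Debye curves and R factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp_st

from helixfit import sequence_tools as st
from helixfit import scattering as sc
from helixfit.helix_builder import build_linear_triple_helix
from conftest import TABLE_SEQUENCES


class TestCoarseGrain:
    def test_cell_with_exactly_cutoff_atoms_yields_one_sphere(self):
        xyz = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2],
                        [0.3, 0.3, 0.3], [0.15, 0.3, 0.2]])
        model = sc.coarse_grain(xyz, box_side=0.53, cutoff=4)
        assert model.n_spheres == 1

    def test_below_cutoff_yields_nothing(self):
        xyz = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2], [0.3, 0.3, 0.3]])
        with pytest.raises(ValueError):
            sc.coarse_grain(xyz, box_side=0.53, cutoff=4)

    def test_invalid_box_raises(self):
        with pytest.raises(ValueError):
            sc.coarse_grain(np.zeros((5, 3)), box_side=0.0)

    def test_radius_conserves_cell_volume(self, pog10_dry):
        v_sphere = 4.0 / 3.0 * np.pi * pog10_dry.radius ** 3
        assert v_sphere == pytest.approx(0.53 ** 3, rel=1e-12)

    @pytest.mark.parametrize("name", sorted(TABLE_SEQUENCES))
    def test_dry_volume_conserved_within_5pc(self, name):
        chain = st.parse_peptide(TABLE_SEQUENCES[name])
        model = build_linear_triple_helix(chain)
        dry = sc.coarse_grain(model)
        target = st.trimer_mass(chain) * st.partial_specific_volume(chain) \
            * 1.66054e-3
        assert dry.dry_volume == pytest.approx(target, rel=0.05)

    def test_translation_stability_of_rg(self, pog10_model):
        rgs = []
        for shift in ([0, 0, 0], [0.19, 0.07, 0.31], [-0.11, 0.23, -0.05]):
            m = pog10_model.transformed(translation=np.array(shift))
            rgs.append(sc.coarse_grain(m).rg())
        assert max(rgs) / min(rgs) - 1 < 0.005


class TestHydration:
    def test_zero_hydration_is_identity(self, pog10_dry):
        out = sc.add_hydration(pog10_dry, 8000.0, hydration=0.0)
        assert out.n_spheres == pog10_dry.n_spheres
        assert out.contrast == "hydrated"

    def test_water_volume_bookkeeping(self, pog10_chain, pog10_dry):
        mass = st.trimer_mass(pog10_chain)
        hyd = sc.add_hydration(pog10_dry, mass)
        added = hyd.hydration_mask.sum() * hyd.box_side ** 3
        target = 0.3 * mass * 1.66054e-3
        assert 0.98 <= added / target <= 1.02 or \
            abs(added - target) <= hyd.box_side ** 3

    def test_hydrated_rg_exceeds_dry_rg(self, pog10_dry, pog10_hydrated):
        assert pog10_hydrated.rg() > pog10_dry.rg()

    def test_hydration_spheres_touch_the_dry_surface(self, pog10_hydrated):
        from scipy.spatial import cKDTree
        dry = pog10_hydrated.centres[~pog10_hydrated.hydration_mask]
        hyd = pog10_hydrated.centres[pog10_hydrated.hydration_mask]
        d, _ = cKDTree(dry).query(hyd)
        assert d.max() <= np.sqrt(3) * pog10_hydrated.box_side + 1e-9

    def test_deterministic_placement(self, pog10_chain, pog10_dry):
        mass = st.trimer_mass(pog10_chain)
        a = sc.add_hydration(pog10_dry, mass)
        b = sc.add_hydration(pog10_dry, mass)
        assert np.array_equal(a.centres, b.centres)


class TestDebye:
    def test_single_sphere_is_form_factor(self):
        sm = sc.SphereModel(np.zeros((1, 3)), 0.5, np.zeros(1, dtype=bool))
        q = np.linspace(0.05, 4.0, 50)
        c = sc.debye_curve(sm, q)
        assert np.allclose(c.i, sc.sphere_form_factor_sq(q, 0.5))
        low = sc.debye_curve(sm, np.array([1e-4]))
        assert low.i[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_sphere_closed_form(self):
        d = 2.0
        sm = sc.SphereModel(np.array([[0, 0, 0], [0, 0, d]]), 0.4,
                            np.zeros(2, dtype=bool))
        q = np.linspace(0.05, 4.0, 80)
        c = sc.debye_curve(sm, q, method="exact")
        g = sc.sphere_form_factor_sq(q, 0.4)
        expected = g * (2 + 2 * np.sin(q * d) / (q * d)) / 4.0
        assert np.allclose(c.i, expected, rtol=1e-12)

    def test_histogram_matches_exact_double_sum(self, random_sphere_model):
        q = np.linspace(0.04, 4.0, 100)
        ih = sc.debye_curve(random_sphere_model, q, method="histogram").i
        ie = sc.debye_curve(random_sphere_model, q, method="exact").i
        assert np.abs(ih / ie - 1).max() < 1e-3

    def test_invariant_under_rigid_motion(self, random_sphere_model):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [1.0, 0.5, 0.3]).as_matrix()
        q = np.linspace(0.04, 4.0, 60)
        a = sc.debye_curve(random_sphere_model, q).i
        moved = sc.SphereModel(random_sphere_model.centres @ rot.T + 7.0,
                               random_sphere_model.radius,
                               random_sphere_model.hydration_mask)
        b = sc.debye_curve(moved, q).i
        assert np.allclose(a, b, rtol=1e-9)

    def test_positive_and_monotone_at_low_q(self, pog10_hydrated):
        q = np.linspace(0.04, 1.0, 120)
        c = sc.debye_curve(pog10_hydrated, q)
        assert (c.i > 0).all()
        guinier = q <= 1.3 / pog10_hydrated.rg()
        assert (np.diff(c.i[guinier]) < 0).all()

    def test_empty_model_raises(self):
        sm = sc.SphereModel(np.zeros((1, 3)), 0.5, np.zeros(1, dtype=bool))
        with pytest.raises(ValueError):
            sc.debye_curve(sm, np.array([-0.1, 0.5]))


class TestRFactor:
    def test_identical_curves_give_zero(self, pog10_hydrated):
        c = sc.debye_curve(pog10_hydrated, np.linspace(0.04, 4, 100))
        res = sc.r_factor(c, c)
        assert res.r_factor == pytest.approx(0.0, abs=1e-4)
        assert res.eta == pytest.approx(1.0, rel=1e-3)

    @settings(deadline=None, max_examples=20)
    @given(scale=hyp_st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        q = np.linspace(0.1, 2.0, 50)
        i = np.exp(-q ** 2) + 0.01
        a = sc.ScatteringCurve(q, i)
        b = sc.ScatteringCurve(q, scale * i)
        res = sc.r_factor(a, b)
        assert res.r_factor < 1e-3
        assert res.eta == pytest.approx(1.0 / scale, rel=1e-3)

    def test_disjoint_q_ranges_raise(self):
        a = sc.ScatteringCurve(np.linspace(0.1, 0.5, 10), np.ones(10))
        b = sc.ScatteringCurve(np.linspace(1.0, 2.0, 10), np.ones(10))
        with pytest.raises(ValueError):
            sc.r_factor(a, b)

    def test_zero_iff_proportional(self):
        q = np.linspace(0.1, 2.0, 50)
        a = sc.ScatteringCurve(q, np.exp(-q ** 2))
        b = sc.ScatteringCurve(q, np.exp(-q ** 2) * (1 + 0.1 * q))
        assert sc.r_factor(a, b).r_factor > 0.5


class TestCurveIO:
    def test_three_column_roundtrip(self, tmp_path):
        q = np.linspace(0.05, 2.0, 30)
        c = sc.ScatteringCurve(q, np.exp(-q), 0.01 * np.exp(-q),
                               contrast="dry", label="x")
        p = tmp_path / "c.dat"
        sc.write_curve(c, p)
        back = sc.read_curve(p, contrast="dry")
        assert np.allclose(back.q, c.q, rtol=1e-5)
        assert np.allclose(back.i, c.i, rtol=1e-5)
        assert np.allclose(back.sigma, c.sigma, rtol=1e-4)

    def test_reads_gnom_style_four_columns_and_comments(self, tmp_path):
        p = tmp_path / "gnom.dat"
        p.write_text("# a comment line\n"
                     "0.10 1.00 0.01 0.99\n"
                     "0.20 0.80 0.01 0.79\n"
                     "0.30 0.55 0.01 0.56\n")
        c = sc.read_curve(p)
        assert len(c.q) == 3 and c.i[1] == 0.80

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "e.dat"
        p.write_text("# nothing\n")
        with pytest.raises(ValueError):
            sc.read_curve(p)
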