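"""1D mesh construction: PCHIP resampling, trimming, serialisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.interpolate import PchipInterpolator

import autoffr as af
from autoffr.centerline import Branch, CenterlineTree
from autoffr.mesh import Mesh1D, Vessel1D, build_mesh1d


def straight_branch(length_mm=100.0, n=51, radii_mm=None):
    z = np.linspace(0, length_mm, n)
    pts = np.column_stack([np.zeros(n), np.zeros(n), z])
    r = np.full(n, 2.0) if radii_mm is None else np.asarray(radii_mm, dtype=float)
    return Branch(pts, r)


class TestBuild:
    def test_linear_radius_profile_reproduced(self):
        r = np.linspace(3.0, 1.0, 51)
        tree = CenterlineTree([straight_branch(radii_mm=r)])
        mesh = build_mesh1d(tree, spacing=0.05, trim_nodes=0)
        v = mesh.vessels[0]
        expected = 0.3 + (0.1 - 0.3) * v.x / v.x[-1]
        np.testing.assert_allclose(v.r0, expected, rtol=1e-6)

    def test_no_undershoot_below_sampled_minimum(self):
        r = np.array([4.0, 4.0, 2.0, 4.0, 4.0])
        tree = CenterlineTree([straight_branch(length_mm=40, n=5, radii_mm=r)])
        mesh = build_mesh1d(tree, spacing=0.01, trim_nodes=0)
        assert mesh.vessels[0].r0.min() >= 0.2 - 1e-9  # cm; PCHIP does not overshoot
        assert mesh.vessels[0].r0.min() == pytest.approx(0.2, abs=1e-9)

    def test_node_count_matches_spacing(self):
        tree = CenterlineTree([straight_branch(length_mm=100.0)])  # 10 cm
        mesh = build_mesh1d(tree, spacing=0.01, trim_nodes=0)
        assert abs(mesh.vessels[0].n_nodes - 1001) <= 1

    def test_nodes_equidistant_within_5pct(self):
        tree = CenterlineTree([straight_branch(length_mm=97.3)])
        mesh = build_mesh1d(tree, spacing=0.05, trim_nodes=0)
        dx = np.diff(mesh.vessels[0].x)
        assert np.all(np.abs(dx - 0.05) <= 0.05 * 0.05)

    def test_root_trim_removes_ostial_nodes(self):
        tree = CenterlineTree([straight_branch()])
        full = build_mesh1d(tree, spacing=0.05, trim_nodes=0)
        trimmed = build_mesh1d(tree, spacing=0.05, trim_nodes=5)
        assert full.vessels[0].n_nodes - trimmed.vessels[0].n_nodes == 5

    def test_root_selected_nearest_reference(self):
        r = np.linspace(3.0, 1.0, 51)
        tree = CenterlineTree([straight_branch(radii_mm=r)])
        near_start = build_mesh1d(tree, spacing=0.05, trim_nodes=0,
                                  root_point=np.array([0, 0, -5.0]))
        near_end = build_mesh1d(tree, spacing=0.05, trim_nodes=0,
                                root_point=np.array([0, 0, 105.0]))
        assert near_start.vessels[0].r0[0] > near_start.vessels[0].r0[-1]
        assert near_end.vessels[0].r0[0] < near_end.vessels[0].r0[-1]


@given(st.lists(st.floats(1.0, 5.0), min_size=4, max_size=12))
def test_pchip_resampling_stays_within_data_range(radii):
    radii = np.asarray(radii)
    tree = CenterlineTree([straight_branch(length_mm=60, n=len(radii), radii_mm=radii)])
    mesh = build_mesh1d(tree, spacing=0.02, trim_nodes=0)
    r_cm = mesh.vessels[0].r0
    assert r_cm.min() >= radii.min() * 0.1 - 1e-9
    assert r_cm.max() <= radii.max() * 0.1 + 1e-9


class TestPchipOracle:
    def test_matches_direct_pchip_evaluation(self):
        """Resampled radii equal an independently constructed PCHIP interpolant."""
        r = np.array([2.0, 2.5, 1.2, 3.0, 2.8, 2.0])
        tree = CenterlineTree([straight_branch(length_mm=50, n=6, radii_mm=r)])
        mesh = build_mesh1d(tree, spacing=0.025, trim_nodes=0)
        v = mesh.vessels[0]
        oracle = PchipInterpolator(np.linspace(0, 5.0, 6), r * 0.1)
        np.testing.assert_allclose(v.r0, oracle(v.x), rtol=1e-9)


class TestMesh1D:
    def test_a0_is_pi_r0_squared(self):
        v = Vessel1D(0, np.array([0.0, 0.1, 0.2]), np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(v.A0, np.pi * 0.04)

    def test_json_round_trip(self, tmp_path):
        mesh = af.make_bifurcation_mesh1d()
        path = str(tmp_path / "mesh.json")
        mesh.to_json(path)
        back = Mesh1D.from_json(path)
        assert len(back.vessels) == len(mesh.vessels)
        for a, b in zip(mesh.vessels, back.vessels):
            np.testing.assert_allclose(a.x, b.x)
            np.testing.assert_allclose(a.r0, b.r0)
            assert a.parent == b.parent

    def test_unknown_vessel_id_lists_valid_ids(self):
        mesh = af.make_bifurcation_mesh1d()
        with pytest.raises(KeyError, match="valid ids"):
            mesh.vessel(99)

    def test_terminals_and_roots(self):
        mesh = af.make_bifurcation_mesh1d()
        assert [v.vessel_id for v in mesh.roots()] == [0]
        assert sorted(v.vessel_id for v in mesh.terminals()) == [1, 2]

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            Vessel1D(0, np.array([0.0, 0.1]), np.array([0.1, 0.0]))


class TestStenosedMesh:
    def test_severity_zero_uniform(self):
        mesh, rmin, _ = af.make_stenosed_mesh1d(r0=0.15, severity=0.0)
        assert np.all(mesh.vessels[0].r0 == 0.15)
        assert rmin == 0.15

    def test_throat_radius_and_location(self):
        mesh, rmin, xc = af.make_stenosed_mesh1d(r0=0.15, severity=0.5, length=10.0)
        assert rmin == pytest.approx(0.075)
        v = mesh.vessels[0]
        assert v.r0.min() == pytest.approx(0.075, rel=1e-9)
        assert v.x[np.argmin(v.r0)] == pytest.approx(xc, abs=v.spacing)

    def test_area_ratio_is_one_minus_severity_squared(self):
        mesh, _, _ = af.make_stenosed_mesh1d(r0=0.2, severity=0.3)
        v = mesh.vessels[0]
        assert v.A0.min() / v.A0.max() == pytest.approx((1 - 0.3) ** 2, rel=1e-9)

    def test_severity_one_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            af.make_stenosed_mesh1d(severity=1.0)
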