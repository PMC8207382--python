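"""Geometry of the helicospiral: centers, circles, visible arc, mesh."""

import json
import math

import numpy as np
import pytest

from shellbands import ShellParams, aperture_center, aperture_circle, visible_arc
from shellbands.helicospiral import (
    DegenerateGeometryError,
    FALLBACK_PHI_UMBILICUS,
    circle_point,
    surface_mesh,
    visible_arc_many,
    whorl_increments,
)
from shellbands.banding import band_sectors

TWO_PI = 2.0 * math.pi


class TestApertureCenter:
    def test_at_origin_angle(self):
        p = ShellParams(r0=2, z0=1, g_r=0.1, g_z=0.1, a0=0.5, g_a=0.1, theta_max=8 * math.pi)
        assert aperture_center(p, 0.0) == pytest.approx([2.0, 0.0, -1.0])

    def test_zero_radial_growth_is_helix(self):
        p = ShellParams(r0=1.5, z0=1, g_r=0.0, g_z=0.05, a0=0.3, g_a=0.0, theta_max=8 * math.pi)
        for theta in np.linspace(0, 8 * math.pi, 17):
            c = aperture_center(p, theta)
            assert np.hypot(c[0], c[1]) == pytest.approx(1.5, abs=1e-12)

    def test_radial_distance_closed_form(self):
        # e^{0.2 pi} evaluated independently at high precision
        p = ShellParams(r0=1, z0=1, g_r=0.1, g_z=0.1, a0=0.3, g_a=0.1, theta_max=8 * math.pi)
        c = aperture_center(p, TWO_PI)
        assert np.hypot(c[0], c[1]) == pytest.approx(1.8744560875853382, abs=1e-12)

    def test_chirality_flips_y(self):
        kw = dict(r0=1, z0=1, g_r=0.1, g_z=0.1, a0=0.3, g_a=0.1, theta_max=8 * math.pi)
        cd = aperture_center(ShellParams(**kw), 1.0)
        cs = aperture_center(ShellParams(chirality="sinistral", **kw), 1.0)
        assert cs[1] == pytest.approx(-cd[1])
        assert cs[0] == pytest.approx(cd[0])

    def test_theta_out_of_range(self):
        p = ShellParams(r0=1, z0=1, g_r=0.1, g_z=0.1, a0=0.3, g_a=0.1, theta_max=8 * math.pi)
        with pytest.raises(ValueError):
            aperture_center(p, -0.1)
        with pytest.raises(ValueError):
            aperture_center(p, 9 * math.pi)


class TestApertureCircle:
    def test_topmost_point_at_phi_zero(self):
        p = ShellParams(r0=2, z0=1, g_r=0.1, g_z=0.1, a0=1.0, g_a=0.0, theta_max=8 * math.pi)
        pts = aperture_circle(p, math.pi, n=4)
        center = aperture_center(p, math.pi)
        assert pts[0] == pytest.approx(center + [0, 0, 1.0], abs=1e-12)

    def test_points_equidistant_from_center(self, iso_shell):
        theta = 5.3
        pts = aperture_circle(iso_shell, theta, n=64)
        center = aperture_center(iso_shell, theta)
        a = iso_shell.a(theta)
        d = np.linalg.norm(pts - center, axis=1)
        assert np.all(np.abs(d - a) < 1e-12)

    def test_radius_closed_form(self):
        p = ShellParams(r0=2, z0=1, g_r=0.1, g_z=0.1, a0=0.5, g_a=0.1, theta_max=8 * math.pi)
        pts = aperture_circle(p, TWO_PI, n=8)
        center = aperture_center(p, TWO_PI)
        d = np.linalg.norm(pts - center, axis=1)
        assert d == pytest.approx(0.9372280437926691, abs=1e-12)  # 0.5 e^{0.2 pi}

    def test_too_few_points(self, iso_shell):
        with pytest.raises(ValueError):
            aperture_circle(iso_shell, 1.0, n=2)


class TestVisibleArc:
    def test_fallback_when_whorls_do_not_touch(self):
        # a tiny aperture never reaches the previous whorl
        p = ShellParams(r0=5, z0=5, g_r=0.02, g_z=0.02, a0=0.05, g_a=0.02, theta_max=8 * math.pi)
        arc = visible_arc(p, p.theta_max)
        assert not arc.intersects
        assert arc.phi_suture == pytest.approx(0.0)
        assert arc.phi_umbilicus == pytest.approx(FALLBACK_PHI_UMBILICUS)
        assert arc.arc_length == pytest.approx(p.a(p.theta_max) * FALLBACK_PHI_UMBILICUS)

    def test_isometric_endpoint_invariance(self, iso_shell):
        a1 = visible_arc(iso_shell, iso_shell.theta_max)
        a2 = visible_arc(iso_shell, iso_shell.theta_max - TWO_PI)
        assert a1.intersects and a2.intersects
        assert a1.phi_suture == pytest.approx(a2.phi_suture, abs=1e-9)
        assert a1.phi_umbilicus == pytest.approx(a2.phi_umbilicus, abs=1e-9)

    def test_isometric_arc_length_scaling(self, iso_shell):
        a1 = visible_arc(iso_shell, iso_shell.theta_max)
        a2 = visible_arc(iso_shell, iso_shell.theta_max - TWO_PI)
        assert a1.arc_length / a2.arc_length == pytest.approx(
            math.exp(TWO_PI * iso_shell.g_a), abs=1e-9
        )

    def test_suture_above_umbilicus(self, iso_shell, allo_shell):
        for p in (iso_shell, allo_shell):
            arc = visible_arc(p, p.theta_max)
            top = circle_point(p, p.theta_max, arc.phi_suture)
            bot = circle_point(p, p.theta_max, arc.phi_umbilicus)
            assert top[2] > bot[2]

    def test_endpoints_continuous_in_theta(self, allo_shell):
        thetas = np.linspace(4 * math.pi, allo_shell.theta_max, 400)
        phi_s, phi_u, _, inter = visible_arc_many(allo_shell, thetas)
        assert inter.all()
        assert np.max(np.abs(np.diff(phi_s))) < 0.02
        assert np.max(np.abs(np.diff(phi_u))) < 0.02

    def test_coincident_circles_raise(self):
        p = ShellParams(r0=1, z0=1, g_r=0.0, g_z=0.0, a0=0.5, g_a=0.0, theta_max=8 * math.pi)
        with pytest.raises(DegenerateGeometryError):
            visible_arc(p, p.theta_max)

    def test_theta_below_one_whorl_rejected(self, iso_shell):
        with pytest.raises(ValueError):
            visible_arc(iso_shell, math.pi)


class TestSelfSimilarity:
    def test_configuration_scales_by_whorl_factor(self, iso_shell):
        g = iso_shell.g_a
        s = math.exp(TWO_PI * g)
        th = iso_shell.theta_max
        c1 = aperture_center(iso_shell, th)
        c0 = aperture_center(iso_shell, th - TWO_PI)
        # same azimuth: radial distance and depth both scale by s
        assert np.hypot(c1[0], c1[1]) == pytest.approx(s * np.hypot(c0[0], c0[1]), abs=1e-9)
        assert c1[2] == pytest.approx(s * c0[2], abs=1e-9)
        assert iso_shell.a(th) == pytest.approx(s * iso_shell.a(th - TWO_PI), abs=1e-12)


class TestWhorlIncrements:
    def test_no_growth_gives_zero(self):
        p = ShellParams(r0=1, z0=1, g_r=0.0, g_z=0.0, a0=0.4, g_a=0.0, theta_max=8 * math.pi)
        dh, dw = whorl_increments(p, 7.0)
        assert dh == pytest.approx(0.0, abs=1e-12)
        assert dw == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_parameters_give_equal_increments(self):
        p = ShellParams(r0=1.2, z0=1.2, g_r=0.07, g_z=0.07, a0=0.5, g_a=0.09, theta_max=8 * math.pi)
        dh, dw = whorl_increments(p, p.theta_max)
        assert dh == pytest.approx(dw, abs=1e-12)

    def test_axial_allometry_raises_height_increment(self):
        p = ShellParams(r0=1, z0=1, g_r=0.05, g_z=0.10, a0=0.5, g_a=0.05, theta_max=4 * math.pi)
        dh, dw = whorl_increments(p, 4 * math.pi)
        # closed-form evaluation of both expressions
        e = math.exp
        dh_exp = (e(0.10 * 4 * math.pi) - e(0.10 * 2 * math.pi)) + 0.5 * (
            e(0.05 * 4 * math.pi) - e(0.05 * 2 * math.pi)
        )
        dw_exp = (e(0.05 * 4 * math.pi) - e(0.05 * 2 * math.pi)) * 1.5
        assert dh == pytest.approx(dh_exp, abs=1e-12)
        assert dw == pytest.approx(dw_exp, abs=1e-12)
        assert dh > dw

    def test_requires_full_whorl(self, iso_shell):
        with pytest.raises(ValueError):
            whorl_increments(iso_shell, math.pi)


class TestSurfaceMesh:
    def test_vertex_and_face_counts(self, iso_shell):
        mesh = surface_mesh(iso_shell, n_theta=60, n_phi=24)
        assert mesh.vertices.shape == (60 * 24, 3)
        assert mesh.faces.max() < len(mesh.vertices)
        assert mesh.faces.min() >= 0
        assert len(mesh.face_labels) == len(mesh.faces)

    def test_unbanded_mesh_all_gap(self, iso_shell):
        mesh = surface_mesh(iso_shell, bands=None, n_theta=30, n_phi=12)
        assert np.all(mesh.face_labels == 0)

    def test_labels_partition_faces(self, iso_shell, five_bands):
        mesh = surface_mesh(iso_shell, bands=five_bands, n_theta=40, n_phi=48)
        # every face has exactly one label and every band appears
        assert set(np.unique(mesh.face_labels)) == {0, 1, 2, 3, 4, 5}

    def test_band_area_fraction_matches_integral_oracle(self, iso_shell, five_bands):
        n_theta, n_phi = 320, 480
        mesh = surface_mesh(iso_shell, bands=five_bands, n_theta=n_theta, n_phi=n_phi)
        v = mesh.vertices
        f = mesh.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        banded = areas[mesh.face_labels > 0].sum() / areas.sum()

        # independent oracle: integrate the surface area element over the
        # band sectors by 2D quadrature of |x_theta x x_phi|
        sectors = band_sectors(iso_shell, five_bands)
        p = iso_shell
        thetas = np.linspace(0, p.theta_max, 400)
        phis = np.linspace(0, TWO_PI, 720, endpoint=False)
        TH, PH = np.meshgrid(thetas, phis, indexing="ij")
        r, z, a = p.r(TH), p.z(TH), p.a(TH)
        rho = r + a * np.sin(PH)
        # x = rho cos th, y = rho sin th, z = -z + a cos ph
        drho_dth = p.g_r * r + p.g_a * a * np.sin(PH)
        dz_dth = -p.g_z * z + p.g_a * a * np.cos(PH)
        # partials of (x, y, z)
        xt = np.stack(
            [
                drho_dth * np.cos(TH) - rho * np.sin(TH),
                drho_dth * np.sin(TH) + rho * np.cos(TH),
                dz_dth,
            ]
        )
        xp = np.stack(
            [a * np.cos(PH) * np.cos(TH), a * np.cos(PH) * np.sin(TH), -a * np.sin(PH)]
        )
        dA = np.linalg.norm(np.cross(xt, xp, axis=0), axis=0)
        in_band = np.zeros_like(PH, dtype=bool)
        for lo_phi, hi_phi in sectors:
            lo_m, hi_m = np.mod(lo_phi, TWO_PI), np.mod(hi_phi, TWO_PI)
            if lo_m <= hi_m:
                in_band |= (PH >= lo_m) & (PH < hi_m)
            else:
                in_band |= (PH >= lo_m) | (PH < hi_m)
        oracle = dA[in_band].sum() / dA.sum()
        assert banded == pytest.approx(oracle, rel=0.02)


class TestSerialization:
    def test_json_round_trip(self, iso_shell, tmp_path):
        path = tmp_path / "shell.json"
        iso_shell.to_json(path)
        back = ShellParams.from_json(path)
        assert back == iso_shell
        # flat eight-field layout
        data = json.loads(path.read_text())
        assert set(data) == {"r0", "z0", "g_r", "g_z", "a0", "g_a", "theta_max", "chirality"}

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            ShellParams(r0=-1, z0=1, g_r=0.1, g_z=0.1, a0=0.3, g_a=0.1, theta_max=8 * math.pi)
        with pytest.raises(ValueError):
            ShellParams(r0=1, z0=1, g_r=0.1, g_z=0.1, a0=0.3, g_a=0.1, theta_max=math.pi)

    def test_mesh_obj_export(self, iso_shell, five_bands, tmp_path):
        mesh = surface_mesh(iso_shell, bands=five_bands, n_theta=10, n_phi=8)
        path = tmp_path / "shell.obj"
        mesh.export_obj(path)
        text = path.read_text()
        assert text.count("\nv ") + text.startswith("v ") == len(mesh.vertices)
        assert text.count("\nf ") == len(mesh.faces)
        assert "usemtl band_3" in text and "usemtl gap" in text
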