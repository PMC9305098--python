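import dataclasses
import math

import numpy as np
import pytest

from focalsf import trajectory as tj
from focalsf.trajectory import (
    EyeGeometry,
    TrajectoryDomainError,
    WedgeBuilder,
    build_wedge,
    fit_to_eye,
    trace_trajectory,
    vf_point_to_phi0,
)
from focalsf.vf_data import VFLocation


def symmetric_params(params):
    """Hemifield-symmetric variant (inferior mirrors superior)."""
    sup = params.superior
    inf = dataclasses.replace(sup, sign=-1.0)
    return dataclasses.replace(params, superior=sup, inferior=inf)


def radial_params(params):
    """b ~ 0 everywhere: straight radial trajectories."""
    sup = dataclasses.replace(params.superior, beta0=-60.0, beta1=0.0)
    inf = dataclasses.replace(params.inferior, beta0=-60.0, beta1=0.0)
    return dataclasses.replace(params, superior=sup, inferior=inf)


class TestTraceTrajectory:
    @pytest.mark.parametrize("phi0", [-170.0, -90.0, -10.0, 5.0, 45.0, 121.0, 179.0])
    def test_starts_exactly_at_phi0(self, params, phi0):
        assert trace_trajectory(phi0, params, params.r0_deg) == pytest.approx(
            phi0, abs=0
        )

    def test_radial_config_is_straight(self, params):
        rp = radial_params(params)
        r = np.linspace(rp.r0_deg, 30, 50)
        phi = trace_trajectory(77.0, rp, r)
        assert np.allclose(phi, 77.0, atol=1e-10)

    def test_mirrored_config_gives_mirror_curves(self, params):
        sp = symmetric_params(params)
        r = np.linspace(sp.r0_deg, 25, 40)
        up = trace_trajectory(80.0, sp, r)
        down = trace_trajectory(-80.0, sp, r)
        assert np.allclose(up, -down, atol=1e-10)

    def test_monotone_in_r_when_curved(self, params):
        r = np.linspace(params.r0_deg + 1e-6, 30, 200)
        for phi0 in (30.0, 95.0, -70.0, -120.0):
            phi = trace_trajectory(phi0, params, r)
            d = np.diff(phi)
            assert np.all(d > 0) or np.all(d < 0)

    def test_r_below_r0_rejected(self, params):
        with pytest.raises(ValueError):
            trace_trajectory(90.0, params, params.r0_deg - 0.5)

    def test_phi0_outside_range_rejected(self, params):
        with pytest.raises(ValueError, match="outside covered range"):
            trace_trajectory(181.0, params, 10.0)

    def test_noncrossing_one_degree_grid(self, params):
        r = np.linspace(params.r0_deg, 30.0, 120)
        for hemi_grid in (np.arange(1.0, 180.0), -np.arange(1.0, 180.0)[::-1]):
            curves = np.array([trace_trajectory(p, params, r) for p in hemi_grid])
            sep = np.diff(curves, axis=0)
            assert sep.min() > 0


class TestFitToEye:
    def test_identity_for_canonical_geometry(self, transform):
        assert transform.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert transform.scale == pytest.approx(1.0, rel=1e-12)

    def test_rotated_geometry_gives_pure_rotation(self, params, canonical_geometry):
        g = canonical_geometry
        rotated = EyeGeometry(
            fovea_xy=g.fovea_xy,
            disc_xy=g.disc_xy,
            fd_distance_deg=g.fd_distance_deg,
            fd_angle_deg=g.fd_angle_deg + 5.0,
        )
        tr = fit_to_eye(params, rotated)
        assert tr.rotation_deg == pytest.approx(-5.0)
        assert tr.scale == pytest.approx(1.0)

    def test_px_roundtrip(self, transform, rng):
        pts = rng.uniform(0, 960, size=(20, 2))
        back = transform.model_to_px(transform.px_to_model(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_degenerate_geometry_raises(self, params):
        with pytest.raises(ValueError):
            EyeGeometry.from_pixels((10.0, 10.0), (10.0, 10.0), mm_per_px=0.004)

    def test_disc_maps_to_canonical_position(self, params, canonical_geometry):
        tr = fit_to_eye(params, canonical_geometry)
        model = tr.px_to_model(np.array(canonical_geometry.disc_xy))
        assert np.allclose(model, params.canonical_disc_xy_deg, atol=1e-9)


class TestVFPointToPhi0:
    def test_point_on_r0_circle_returns_its_angle(self, params, transform):
        # construct the field point whose retinal image sits on the r0
        # circle at a chosen disc-polar angle
        for target in (37.0, -112.0):
            pt = tj._disc_cartesian(params, params.r0_deg, target)
            # invert field_to_model (identity rotation/scale for canonical
            # geometry): retina (x, y) <- field (x, -y)
            loc = VFLocation(1, float(pt[0]), -float(pt[1]))
            phi0 = vf_point_to_phi0(loc, transform)
            assert phi0 == pytest.approx(target, abs=1e-6)

    def test_roundtrip_all_analysis_locations(self, params, transform, analysis_locs):
        for loc in analysis_locs:
            phi0 = vf_point_to_phi0(loc, transform)
            pt = transform.field_to_model(loc.x_deg, loc.y_deg)
            r, phi = tj._disc_polar(params, pt)
            r, phi = float(np.ravel(r)[0]), float(np.ravel(phi)[0])
            assert abs(trace_trajectory(phi0, params, r) - phi) < 0.5

    def test_superior_field_maps_to_inferior_retina(self, transform, analysis_locs):
        for loc in analysis_locs:
            if loc.y_deg >= 9.0:
                assert vf_point_to_phi0(loc, transform) < 0
            if loc.y_deg <= -9.0:
                assert vf_point_to_phi0(loc, transform) > 0

    def test_blind_spot_rejected(self, transform, grid_right):
        blind = next(l for l in grid_right if l.is_blind_spot)
        with pytest.raises(ValueError, match="blind-spot"):
            vf_point_to_phi0(blind, transform)

    def test_coverage_gap_without_nasal_taper(self, params, canonical_geometry):
        bare = dataclasses.replace(params, nasal_taper_deg=0.0)
        tr = fit_to_eye(bare, canonical_geometry)
        loc = VFLocation(47, 21.0, -3.0)
        with pytest.raises(TrajectoryDomainError, match="coverage gap"):
            vf_point_to_phi0(loc, tr, bare)


class TestWedges:
    MAP = (240, 240)
    MMPP = 4.11 / 240

    def builder(self, transform, params=None):
        return WedgeBuilder(
            transform, self.MAP, self.MMPP, disc_xy_px=(120.0, 120.0), params=params
        )

    def test_mask_shrinks_as_variability_vanishes(self, params, transform):
        loc = VFLocation(34, 3.0, 3.0)
        areas = []
        for sd in (5.0, 2.0, 0.5, 0.1):
            p = dataclasses.replace(params, variability_sd_deg=sd)
            b = WedgeBuilder(transform, self.MAP, self.MMPP, (120.0, 120.0), p)
            areas.append(b.wedge(loc).pixel_mask.sum())
        assert areas == sorted(areas, reverse=True)
        assert areas[-1] < areas[0] / 10

    def test_ring_arc_equals_phi0_interval_for_radial_config(self, params, transform):
        rp = radial_params(params)
        b = self.builder(transform, rp)
        w = b.wedge(VFLocation(55, 9.0, -9.0))
        assert w.ring_arc_width == pytest.approx(w.phi0_hi - w.phi0_lo, abs=1e-6)

    def test_mirror_symmetric_wedges(self, params, transform):
        sp = symmetric_params(params)
        # symmetric geometry too: disc on the horizontal through the fovea
        g = transform.geometry
        geom = EyeGeometry(g.fovea_xy, g.disc_xy, g.fd_distance_deg, 0.0)
        sp = dataclasses.replace(sp, canonical_disc_xy_deg=(15.0, 0.0))
        tr = fit_to_eye(sp, geom)
        b = WedgeBuilder(tr, self.MAP, self.MMPP, (119.5, 119.5), sp)
        up = b.wedge(VFLocation(24, 3.0, 9.0))
        down = b.wedge(VFLocation(54, 3.0, -9.0))
        assert up.phi0_center == pytest.approx(-down.phi0_center, abs=1e-6)
        assert np.array_equal(up.pixel_mask, np.flipud(down.pixel_mask))

    def test_mask_support_within_phi0_bounds(self, transform, analysis_locs):
        b = self.builder(transform)
        phi0_field, _ = b.phi0_field()
        for loc in analysis_locs[::7]:
            w = b.wedge(loc)
            vals = phi0_field[w.pixel_mask & ~np.isnan(phi0_field)]
            assert vals.size
            assert vals.min() >= w.phi0_lo - 0.3
            assert vals.max() <= w.phi0_hi + 0.3

    def test_adjacent_wedges_overlap(self, transform):
        b = self.builder(transform)
        w1 = b.wedge(VFLocation(34, 3.0, 3.0))
        w2 = b.wedge(VFLocation(33, -3.0, 3.0))
        assert (w1.pixel_mask & w2.pixel_mask).sum() > 0

    def test_build_wedge_convenience_matches_builder(self, transform):
        loc = VFLocation(34, 3.0, 3.0)
        w1 = build_wedge(loc, transform, self.MAP, self.MMPP, disc_xy_px=(120.0, 120.0))
        w2 = self.builder(transform).wedge(loc)
        assert np.array_equal(w1.pixel_mask, w2.pixel_mask)
        assert w1.ring_arc == w2.ring_arc

    def test_roi_outside_field_errors(self, transform, params):
        b = WedgeBuilder(transform, (16, 16), 0.001, disc_xy_px=(8.0, 8.0))
        with pytest.raises(ValueError, match="ROI outside field"):
            b.wedge(VFLocation(1, -9.0, 27.0))


class TestGeometryIngest:
    def test_read_geometry_csv(self, tmp_path):
        p = tmp_path / "geometry.csv"
        p.write_text(
            "subject_id,eye,fovea_x_px,fovea_y_px,disc_x_px,disc_y_px\n"
            "S1,right,-50.0,520.0,480.0,450.0\n"
        )
        geoms = tj.read_geometry_csv(p, {"S1": 4.11 / 960})
        assert "S1" in geoms
        assert geoms["S1"].fd_distance_deg == pytest.approx(8.3532, abs=1e-3)
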