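"""Projection geometry, membrane angles, photobleach and profile registration."""

import numpy as np
import pytest

from endotrack import (
    CellGeometry,
    MembraneContour,
    Trajectory,
    align_photobleach,
    membrane_angle,
    projection_underestimate,
    register_membrane_profiles,
)
from endotrack.geometry import DegenerateDirectionError
from endotrack.profiles import MembraneProfile, synthetic_profile_series
from endotrack.simulate import make_template, template_average


class TestProjection:
    def test_depth_of_field_edge_is_half_percent(self):
        pct = 100.0 * projection_underestimate(250.0, CellGeometry(2500.0, 500.0))
        assert pct == pytest.approx(0.5, abs=0.01)

    def test_equatorial_event_unprojected(self):
        assert projection_underestimate(0.0) == 0.0

    def test_closed_form_at_large_offset(self):
        # 1 - sqrt(1 - 0.36) = 0.2
        assert projection_underestimate(1500.0, CellGeometry(2500.0, 3000.0)) == pytest.approx(0.2)

    def test_monotone_in_offset(self):
        vals = [projection_underestimate(z, CellGeometry(2500.0, 5000.0)) for z in np.linspace(0, 2400, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            projection_underestimate(2600.0, CellGeometry(2500.0, 5000.0))


def radial_track(contour_radius, angle_deg, length=50.0, n=10, center=(0.0, 0.0)):
    """Straight track starting at the membrane and moving inward at the given
    angle to the local tangent."""
    theta = 0.3  # position on the circle
    base = np.array([contour_radius * np.cos(theta), contour_radius * np.sin(theta)])
    tangent = np.array([-np.sin(theta), np.cos(theta)])
    inward = -np.array([np.cos(theta), np.sin(theta)])
    ang = np.radians(angle_deg)
    direction = np.cos(ang) * tangent + np.sin(ang) * inward
    steps = np.linspace(0, length, n)
    pts = base + steps[:, None] * direction
    return Trajectory(id="trk", t=np.arange(n) * 0.25, x=pts[:, 0] + center[0], y=pts[:, 1] + center[1], f=np.ones(n))


class TestMembraneAngle:
    contour = MembraneContour.circle(2500.0, n=720)

    def test_normal_track_is_ninety_degrees(self):
        ang = membrane_angle(radial_track(2500.0, 90.0), self.contour)
        assert ang == pytest.approx(90.0, abs=0.5)

    def test_tangential_track_is_zero_degrees(self):
        # a straight 50 nm chord deviates from the local arc tangent by
        # ~ length / (2 R) radians, so allow that geometric offset
        ang = membrane_angle(radial_track(2500.0, 0.0), self.contour)
        assert ang == pytest.approx(0.0, abs=1.5)

    def test_rigid_motion_invariance(self):
        from endotrack import RigidTransform

        trk = radial_track(2500.0, 35.0)
        a0 = membrane_angle(trk, self.contour)
        S = RigidTransform(1.2, 500.0, -300.0)
        x, y = S.apply(trk.x, trk.y)
        vx, vy = S.apply(self.contour.vertices[:, 0], self.contour.vertices[:, 1])
        a1 = membrane_angle(trk.replace(x=x, y=y), MembraneContour(np.column_stack([vx, vy])))
        assert a1 == pytest.approx(a0, abs=0.5)

    def test_uniform_orientations_average_forty_five(self, rng):
        angles = [
            membrane_angle(radial_track(2500.0, a), self.contour)
            for a in rng.uniform(0.0, 180.0, 10_000)
        ]
        assert np.mean(angles) == pytest.approx(45.0, abs=1.0)

    def test_degenerate_track_flagged(self):
        n = 8
        trk = Trajectory(id="still", t=np.arange(n) * 0.25, x=np.full(n, 2500.0), y=np.zeros(n), f=np.ones(n))
        with pytest.raises(DegenerateDirectionError):
            membrane_angle(trk, self.contour, noise_floor=1.0)


@pytest.fixture(scope="module")
def oriented_average():
    # template moves along +X (inward); wrap as an average trajectory
    from endotrack.twocolor import orient_to_symmetry_axis

    tpl = make_template(meander_amplitude=0.0)
    avg, _ = orient_to_symmetry_axis(template_average(tpl, sem_xy=1.0), center=False)
    return avg


class TestPhotobleach:
    contour = MembraneContour.circle(2500.0, n=720)

    def _track_from_average(self, avg, jump=0.0, bleach_index=40, rng=None, sigma=0.0):
        """Track whose inward movement follows the average; after the bleach
        frame the inward coordinate is displaced by ``jump``."""
        base, normal = self.contour.inward_normal((2500.0, 0.0))
        s = avg.x - avg.x[0]  # inward movement, starts at the membrane
        s = s + np.where(np.arange(len(s)) >= bleach_index, jump, 0.0)
        if rng is not None and sigma > 0:
            s = s + rng.normal(0, sigma, len(s))
        pts = base[None, :] + s[:, None] * normal[None, :]
        return Trajectory(id="bleach", t=avg.t.copy(), x=pts[:, 0], y=pts[:, 1], f=avg.f.copy())

    def test_self_alignment_zero_offsets(self, oriented_average):
        avg = oriented_average
        trk = self._track_from_average(avg)
        res = align_photobleach(trk, bleach_time=avg.t[40], contour=self.contour, P=avg)
        assert res.lag == 0
        assert res.jump == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.position, avg.x, atol=1e-6)

    def test_constructed_jump_recovered(self, oriented_average, rng):
        avg = oriented_average
        jumps = []
        for _ in range(50):
            trk = self._track_from_average(avg, jump=-20.0, bleach_index=40, rng=rng, sigma=3.0)
            res = align_photobleach(trk, bleach_time=avg.t[40], contour=self.contour, P=avg)
            jumps.append(res.jump)
        assert np.mean(jumps) == pytest.approx(-20.0, abs=2.0)

    def test_post_bleach_only_rejected(self, oriented_average):
        avg = oriented_average
        trk = self._track_from_average(avg)
        with pytest.raises(ValueError, match="pre-bleach"):
            align_photobleach(trk, bleach_time=avg.t[0] - 1.0, contour=self.contour, P=avg)


class SlaTrack:
    """Synthetic coat-protein track crossing given depths at known times."""

    def __init__(self, t, x):
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)


class TestProfileRegistration:
    def test_self_consistent_times_recovered(self):
        profiles = synthetic_profile_series(n_profiles=5, max_depth=120.0)
        band = 35.0
        coms = []
        for prof in profiles:
            if prof.depth <= 0:
                coms.append(0.0)
            else:
                total = prof.total_arclength
                coms.append(prof.band_com(max(0.0, total - band), total))
        # construct a track that passes each tip centre of mass at t = its index
        t = np.linspace(0.0, 4.0, 200)
        x = np.interp(t, np.arange(5.0), coms)
        reg = register_membrane_profiles(profiles, SlaTrack(t, x), rvs_curve=None)
        np.testing.assert_allclose(reg.times, np.arange(5.0), atol=0.05)
        assert reg.origin == pytest.approx(0.0)

    def test_flat_profile_gets_start_time(self):
        flat = MembraneProfile(z=[0.0, 0.0], rho=[60.0, 0.0])
        track = SlaTrack([2.0, 3.0, 4.0], [0.0, 50.0, 100.0])
        reg = register_membrane_profiles([flat], track)
        assert reg.times[0] == pytest.approx(2.0)

    def test_ordering_preserved_and_unreachable_flagged(self):
        profiles = synthetic_profile_series(n_profiles=6, max_depth=200.0)
        t = np.linspace(0.0, 10.0, 100)
        x = np.linspace(0.0, 120.0, 100)  # never reaches the deepest tips
        reg = register_membrane_profiles(profiles, SlaTrack(t, x))
        placed = reg.times[np.isfinite(reg.times)]
        assert np.all(np.diff(placed) >= 0)
        assert len(reg.unplaced) >= 1

    def test_tip_band_com_matches_numerical_quadrature(self):
        """Hemispherical tip: surface centre of mass of 30 vs 40 nm bands vs
        brute-force numerical surface integration."""
        phi = np.linspace(0.0, np.pi / 2, 2000)
        r = 20.0
        tube = np.linspace(0.0, 80.0, 800)
        z = np.concatenate([tube, 80.0 + r * np.sin(phi)[1:]])
        rho = np.concatenate([np.full_like(tube, r), r * np.cos(phi)[1:]])
        prof = MembraneProfile(z=z, rho=rho)
        total = prof.total_arclength
        for band in (30.0, 40.0):
            com = prof.band_com(total - band, total)
            # dense independent quadrature on the same surface
            s_dense = np.linspace(total - band, total, 20_000)
            sv = prof.arclength
            rho_d = np.interp(s_dense, sv, prof.rho)
            z_d = np.interp(s_dense, sv, prof.z)
            oracle = np.trapezoid(rho_d * z_d, s_dense) / np.trapezoid(rho_d, s_dense)
            assert com == pytest.approx(oracle, abs=0.5)
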