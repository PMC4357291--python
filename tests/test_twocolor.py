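"""Two-color alignment: warps, pair fits, median aggregation, propagation."""

import numpy as np
import pytest

from endotrack import (
    RigidTransform,
    Trajectory,
    TrajectoryPair,
    TransformEstimate,
    aggregate_transforms,
    apply_alignment,
    average_nonmotile,
    build_warp,
    orient_to_symmetry_axis,
    pair_lag_and_fit,
)
from endotrack.simulate import SyntheticConfig, _canonical_averages, _make_pair
from endotrack.twocolor import PairTransforms

MAD_TO_SD = 1.4826


@pytest.fixture(scope="module")
def canonical():
    cfg = SyntheticConfig(sigma_p=10.0, sigma_r=19.0, seed=42)
    P, R, _ = _canonical_averages(cfg)
    return cfg, P, R


class TestWarp:
    def test_pure_translation_recovered_exactly(self, rng):
        b = rng.uniform(0, 1000, (10, 2))
        a = b + np.array([10.0, -5.0])
        warp = build_warp(a, b, kind="affine")
        np.testing.assert_allclose(warp(b), a, atol=1e-9)
        assert warp.rms < 1e-9

    def test_identity_control_points(self, rng):
        pts = rng.uniform(0, 1000, (12, 2))
        for kind in ("affine", "lwm"):
            warp = build_warp(pts, pts, kind=kind)
            np.testing.assert_allclose(warp(pts), pts, atol=1e-6)

    def test_lwm_beats_affine_on_quadratic_distortion(self, rng):
        b = rng.uniform(0, 2000, (40, 2))
        # quadratic chromatic distortion field
        a = b + 1e-5 * np.column_stack([b[:, 0] ** 2 - b[:, 1] ** 2, b[:, 0] * b[:, 1]])
        affine = build_warp(a, b, kind="affine")
        lwm = build_warp(a, b, kind="lwm")
        assert lwm.rms < affine.rms

    def test_collinear_points_rejected(self):
        b = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            build_warp(b, b, kind="affine")


class TestOrientation:
    def test_motion_axis_becomes_plus_x(self, canonical):
        _, P, _ = canonical
        rot = RigidTransform(1.1, 300.0, -200.0)
        x, y = rot.apply(P.x, P.y)
        turned = P.replace(x=x, y=y)
        oriented, _ = orient_to_symmetry_axis(turned, center=True)
        # net motion along +X, centred at the weighted centre of mass
        assert oriented.x[-1] > oriented.x[0]
        w = oriented.f / oriented.f.sum()
        assert abs(np.sum(w * oriented.x)) < 1e-6
        np.testing.assert_allclose(
            np.hypot(oriented.x - oriented.x[0], oriented.y - oriented.y[0]),
            np.hypot(P.x - P.x[0], P.y - P.y[0]),
            atol=1e-6,
        )


class TestPairFit:
    def test_identical_pair_gives_identity(self, canonical):
        _, P, R = canonical
        p = Trajectory(id="p", t=P.t.copy(), x=P.x.copy(), y=P.y.copy(), f=P.f.copy())
        r = Trajectory(id="r", t=R.t.copy(), x=R.x.copy(), y=R.y.copy(), f=R.f.copy())
        pt = pair_lag_and_fit(TrajectoryPair(p, r), P, R, smoothing_window=1)
        assert pt.tau_p == 0 and pt.tau_r == 0
        assert pt.T_p.is_identity(tol=1e-6)
        assert pt.T_r.is_identity(tol=1e-6)

    def test_fluorescence_shift_recovers_lag(self, canonical):
        _, P, R = canonical
        k = 4
        f_shifted = np.roll(P.f, k)  # p's curve lags k frames behind
        f_shifted[:k] = 0.0
        p = Trajectory(id="p", t=P.t.copy(), x=P.x.copy(), y=P.y.copy(), f=f_shifted)
        r = Trajectory(id="r", t=R.t.copy(), x=R.x.copy(), y=R.y.copy(), f=R.f.copy())
        pt = pair_lag_and_fit(TrajectoryPair(p, r), P, R, smoothing_window=1)
        assert pt.tau_p == k

    def test_five_point_fit_matches_theta_grid_oracle(self):
        from endotrack.trajectory import AverageTrajectory

        t = np.arange(5) * 0.25
        P = AverageTrajectory(
            t=t,
            x=np.array([0.0, 5.0, 12.0, 20.0, 31.0]),
            y=np.array([1.0, -2.0, 0.5, 3.0, -1.0]),
            f=np.array([1.0, 2.0, 3.0, 2.0, 1.0]),
            dx=np.full(5, 0.8),
            dy=np.full(5, 1.2),
            df=np.full(5, 0.1),
            n=np.full(5, 10),
        )
        R = P
        rot = RigidTransform(0.3, 7.0, -4.0).inverse()
        px, py = rot.apply(P.x, P.y)
        p = Trajectory(id="p", t=t, x=px + [0.5, -0.3, 0.2, -0.4, 0.1], y=py + [0.2, 0.4, -0.1, 0.3, -0.2], f=P.f.copy())
        pt = pair_lag_and_fit(TrajectoryPair(p, p), P, R, min_overlap=3, smoothing_window=1)
        w = P.f * p.f / (P.dx * P.dy)

        def cost(T):
            x, y = T.apply(p.x, p.y)
            return float(np.sum(w * ((P.x - x) ** 2 + (P.y - y) ** 2)) / w.sum())

        got = cost(pt.T_p)
        W = w.sum()
        mp = np.array([np.sum(w * p.x), np.sum(w * p.y)]) / W
        mq = np.array([np.sum(w * P.x), np.sum(w * P.y)]) / W
        best = np.inf
        for theta in np.arange(-np.pi, np.pi, 1e-4):
            c, s = np.cos(theta), np.sin(theta)
            T = RigidTransform(theta, mq[0] - (c * mp[0] - s * mp[1]), mq[1] - (s * mp[0] + c * mp[1]))
            best = min(best, cost(T))
        assert got == pytest.approx(best, rel=1e-6, abs=1e-9)


class TestAggregation:
    def test_identical_transforms_zero_uncertainty(self):
        T = RigidTransform(0.02, 5.0, -3.0)
        pairs = [PairTransforms(tau_p=1, tau_r=3, T_p=RigidTransform(), T_r=T) for _ in range(7)]
        est = aggregate_transforms(pairs, dt=0.5)
        assert est.tau == pytest.approx(1.0)  # (3 - 1) * 0.5 s
        assert est.theta == pytest.approx(0.02)
        assert est.tx == pytest.approx(5.0)
        assert est.ty == pytest.approx(-3.0)
        assert est.dtau == est.dtx == est.dty == est.dtheta == 0.0
        assert est.m == 7

    def test_median_mad_hand_example(self):
        # lags (frames): {-1, 0, 0, 1, 2} at dt = 1 s
        lags = [-1, 0, 0, 1, 2]
        pairs = [
            PairTransforms(tau_p=0, tau_r=lag, T_p=RigidTransform(), T_r=RigidTransform())
            for lag in lags
        ]
        est = aggregate_transforms(pairs, dt=1.0)
        assert est.tau == pytest.approx(0.0)
        assert est.dtau == pytest.approx(MAD_TO_SD * 1.0 / np.sqrt(5), abs=1e-12)  # ~0.663 s

    def test_large_rotation_warns(self):
        pairs = [
            PairTransforms(tau_p=0, tau_r=0, T_p=RigidTransform(), T_r=RigidTransform(0.5, 0, 0))
            for _ in range(3)
        ]
        with pytest.warns(UserWarning, match="small-angle"):
            aggregate_transforms(pairs, dt=1.0)

    def test_exact_composition_formula(self):
        # with matching rotations the median composition equals T_r (T_p)^-1
        T_p = RigidTransform(0.1, 12.0, -7.0)
        T_r = RigidTransform(0.13, -4.0, 9.0)
        pairs = [PairTransforms(tau_p=0, tau_r=0, T_p=T_p, T_r=T_r)] * 5
        est = aggregate_transforms(pairs, dt=1.0)
        expect = T_r.compose(T_p.inverse())
        assert est.theta == pytest.approx(expect.theta, abs=1e-12)
        assert est.tx == pytest.approx(expect.tx, abs=1e-9)
        assert est.ty == pytest.approx(expect.ty, abs=1e-9)

    def test_reported_uncertainty_matches_empirical_scatter(self, canonical):
        """The MAD-based standard errors calibrate the repeat-to-repeat
        scatter of the median estimates within a factor 1.5."""
        cfg, P, R = canonical
        rng = np.random.default_rng(7)
        taus, txs, tys = [], [], []
        dtaus, dtxs, dtys = [], [], []
        for _ in range(30):
            per_pair = [pair_lag_and_fit(_make_pair(P, R, cfg, rng), P, R) for _ in range(50)]
            est = aggregate_transforms(per_pair, dt=cfg.dt)
            taus.append(est.tau)
            txs.append(est.tx)
            tys.append(est.ty)
            dtaus.append(est.dtau)
            dtxs.append(est.dtx)
            dtys.append(est.dty)
        for emp, rep in [(np.std(txs), np.mean(dtxs)), (np.std(tys), np.mean(dtys))]:
            assert rep / 1.5 < emp < rep * 1.5
        # lags are discrete and often exactly recovered; only require the
        # reported tau uncertainty to bound the scatter direction
        assert np.std(taus) <= np.mean(dtaus) * 1.5 + cfg.dt

    @pytest.mark.parametrize("m_pair", [(25, 100), (100, 400)])
    def test_uncertainty_scales_as_inverse_sqrt_m(self, canonical, m_pair):
        cfg, P, R = canonical
        m1, m2 = m_pair

        def mean_dtx(m, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(3):
                per_pair = [pair_lag_and_fit(_make_pair(P, R, cfg, rng), P, R) for _ in range(m)]
                est = aggregate_transforms(per_pair, dt=cfg.dt)
                vals.append(np.hypot(est.dtx, est.dty))
            return np.mean(vals)

        ratio = mean_dtx(m1, 3) / mean_dtx(m2, 4)
        expected = np.sqrt(m2 / m1)
        assert expected / 1.6 < ratio < expected * 1.6


class TestApplyAlignment:
    def test_identity_estimate_returns_input(self, canonical):
        _, P, _ = canonical
        out = apply_alignment(P, TransformEstimate.identity())
        np.testing.assert_allclose(out.x, P.x)
        np.testing.assert_allclose(out.y, P.y)
        np.testing.assert_allclose(out.zx, P.dx)
        np.testing.assert_allclose(out.zy, P.dy)

    def test_zero_errors_give_zero_bands(self, canonical):
        _, P, _ = canonical
        P0 = P.replace(dx=np.zeros(len(P)), dy=np.zeros(len(P)))
        out = apply_alignment(P0, TransformEstimate.identity())
        assert np.all(out.zx == 0) and np.all(out.zy == 0)
        assert np.all(out.ci95_x == 0)

    def test_propagation_matches_monte_carlo(self, canonical, rng):
        """First-order zeta propagation vs direct sampling of the transform
        uncertainty (1e5 draws): positional SDs agree within 5%."""
        _, P, _ = canonical
        est = TransformEstimate(
            tau=0.0, tx=3.0, ty=-2.0, theta=0.01,
            dtau=0.1, dtx=1.1, dty=0.7, dtheta=0.008, m=100,
        )
        out = apply_alignment(P, est)
        n_draw = 100_000
        thetas = est.theta + rng.normal(0, est.dtheta, n_draw)
        txs = est.tx + rng.normal(0, est.dtx, n_draw)
        tys = est.ty + rng.normal(0, est.dty, n_draw)
        for i in [5, len(P) // 2, len(P) - 3]:
            base = rng.normal(0, 1, (n_draw, 2)) * np.array([P.dx[i], P.dy[i]])
            px = P.x[i] + base[:, 0]
            py = P.y[i] + base[:, 1]
            x = np.cos(thetas) * px - np.sin(thetas) * py + txs
            y = np.sin(thetas) * px + np.cos(thetas) * py + tys
            assert np.std(x) == pytest.approx(out.zx[i], rel=0.05)
            assert np.std(y) == pytest.approx(out.zy[i], rel=0.05)


class TestNonMotile:
    def test_identity_pairs_average_to_common_target(self, canonical):
        _, P, R = canonical
        target = Trajectory(id="m", t=R.t.copy(), x=R.x + 30.0, y=R.y.copy(), f=R.f.copy())
        ref = Trajectory(id="r", t=R.t.copy(), x=R.x.copy(), y=R.y.copy(), f=R.f.copy())
        pairs = [TrajectoryPair(target, ref, k) for k in range(4)]
        avg = average_nonmotile(pairs, R, smoothing_window=1)
        np.testing.assert_allclose(avg.x, target.x, atol=1e-6)
        np.testing.assert_allclose(avg.y, target.y, atol=1e-6)

    def test_single_pair_returns_transformed_target(self, canonical):
        _, _, R = canonical
        rot = RigidTransform(0.8, 100.0, -60.0)
        rx, ry = rot.apply(R.x, R.y)
        ref = Trajectory(id="r", t=R.t.copy(), x=rx, y=ry, f=R.f.copy())
        tx_, ty_ = rot.apply(R.x + 30.0, R.y)
        target = Trajectory(id="m", t=R.t.copy(), x=tx_, y=ty_, f=R.f.copy())
        avg = average_nonmotile([TrajectoryPair(target, ref, 0)], R, smoothing_window=1)
        np.testing.assert_allclose(avg.x, R.x + 30.0, atol=1e-6)
        np.testing.assert_allclose(avg.y, R.y, atol=1e-6)

    def test_constructed_offset_recovered_under_random_orientations(self, canonical, rng):
        _, _, R = canonical
        pairs = []
        for k in range(40):
            rot = RigidTransform(float(rng.uniform(0, 2 * np.pi)), *rng.uniform(-300, 300, 2))
            rx, ry = rot.apply(R.x, R.y)
            rx = rx + rng.normal(0, 5.0, len(R))
            ry = ry + rng.normal(0, 5.0, len(R))
            px, py = rot.apply(R.x + 30.0, R.y)
            px = px + rng.normal(0, 5.0, len(R))
            py = py + rng.normal(0, 5.0, len(R))
            pairs.append(
                TrajectoryPair(
                    Trajectory(id=f"p{k}", t=R.t.copy(), x=px, y=py, f=R.f.copy()),
                    Trajectory(id=f"r{k}", t=R.t.copy(), x=rx, y=ry, f=R.f.copy()),
                    k,
                )
            )
        avg = average_nonmotile(pairs, R, smoothing_window=1)
        offset = np.mean(avg.x - R.x)
        assert offset == pytest.approx(30.0, abs=1.5)
        assert abs(np.mean(avg.y - R.y)) < 1.5


def test_noiseless_two_step_alignment_is_exact_identity():
    """Coincident ground truths with zero noise: the full two-color estimate
    is the identity transform with zero uncertainties."""
    from endotrack.simulate import run_alignment_benchmark

    cfg = SyntheticConfig(sigma_p=0.0, sigma_r=0.0, sigma_f=0.0, n_pairs=8, n_repeats=1, seed=0)
    res = run_alignment_benchmark(cfg)
    assert res.tau[0] == 0.0
    assert res.theta[0] == pytest.approx(0.0, abs=1e-12)
    assert res.tx[0] == pytest.approx(0.0, abs=1e-9)
    assert res.ty[0] == pytest.approx(0.0, abs=1e-9)
    assert res.mean_displacement == pytest.approx(0.0, abs=1e-9)
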