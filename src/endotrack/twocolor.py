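"""Two-color alignment of average trajectories with robust error propagation.

Average trajectories of different proteins live in unrelated frames.  They
are registered to the frame of a reference protein (Abp1) through pairs of
trajectories acquired simultaneously in two channels: the pair's reference
track ``r`` is aligned to the reference average ``R``, the pair's target
track ``p`` to the target average ``P``, and the composition
``T = T_r (T_p)^{-1}`` maps ``P`` into ``R``'s frame.  With M pairs the
per-pair estimates are combined by component-wise medians; uncertainties
are 1.4826 x MAD / sqrt(M) (the robust standard error of a median).

The composition formulas for the translation assume the two per-pair
rotations nearly cancel, which holds when both averages are first rotated
to their axis of symmetry (the invagination axis, taken as +X) and the
target average is centred on its fluorescence-weighted centre of mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.transform import AffineTransform

from .align_single import AlignmentError, fit_rigid_weighted
from .trajectory import AverageTrajectory, Trajectory
from .transforms import RigidTransform

__all__ = [
    "TrajectoryPair",
    "PairTransforms",
    "TransformEstimate",
    "AlignedTrajectory",
    "WarpModel",
    "build_warp",
    "orient_to_symmetry_axis",
    "resample_to_grid",
    "pair_lag_and_fit",
    "aggregate_transforms",
    "apply_alignment",
    "average_nonmotile",
]

log = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor: MAD of a normal sample -> SD


@dataclass
class TrajectoryPair:
    """Simultaneously acquired target (``p``) and reference (``r``) tracks."""

    target: Trajectory
    reference: Trajectory
    acquisition_id: object = None

    def __post_init__(self):
        if abs(self.target.dt - self.reference.dt) > 1e-9:
            raise ValueError("pair channels must share the sampling interval")


@dataclass(frozen=True)
class PairTransforms:
    """Per-pair lags and rigid fits onto the two average trajectories."""

    tau_p: int
    tau_r: int
    T_p: RigidTransform
    T_r: RigidTransform


@dataclass(frozen=True)
class TransformEstimate:
    """Median/MAD-aggregated transform aligning the target average to the reference.

    ``tau`` is in seconds, ``tx, ty`` in nm, ``theta`` in radians; the
    ``d*`` fields are the corresponding standard errors; ``m`` is the
    number of trajectory pairs used.
    """

    tau: float
    tx: float
    ty: float
    theta: float
    dtau: float
    dtx: float
    dty: float
    dtheta: float
    m: int

    @property
    def transform(self) -> RigidTransform:
        return RigidTransform(self.theta, self.tx, self.ty)

    @classmethod
    def identity(cls) -> "TransformEstimate":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1)


@dataclass
class AlignedTrajectory:
    """Target average trajectory expressed in the reference frame.

    ``zx, zy`` are the positional standard errors with the alignment
    uncertainty propagated on top of the averaging SEMs (so ``zx >= dx``);
    ``zf`` equals the fluorescence SEM.  95% bands are 1.96 x z.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    f: np.ndarray
    zx: np.ndarray
    zy: np.ndarray
    zf: np.ndarray
    dtau: float = 0.0

    def __len__(self):
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def ci95_x(self) -> np.ndarray:
        return 1.96 * self.zx

    @property
    def ci95_y(self) -> np.ndarray:
        return 1.96 * self.zy


# ---------------------------------------------------------------------------
# Chromatic registration


@dataclass
class WarpModel:
    """Spatial warp mapping channel-B coordinates onto channel A.

    Estimated from matched control points (multicolour beads imaged in both
    channels).  ``kind`` is ``"affine"`` or ``"lwm"`` (local weighted mean:
    second-order polynomial fits around each control point, blended with a
    cubic radial weight, after MATLAB's ``cp2tform`` lwm method).
    ``residuals`` holds leave-one-out residual magnitudes per control point.
    """

    kind: str
    src: np.ndarray  # channel B control points
    dst: np.ndarray  # channel A control points
    n_neighbors: int = 12
    residuals: np.ndarray = field(default=None, repr=False)
    _affine: object = field(default=None, repr=False)
    _polys: np.ndarray = field(default=None, repr=False)
    _radii: np.ndarray = field(default=None, repr=False)

    def __call__(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if self.kind == "affine":
            return self._affine(pts)
        return _lwm_eval(pts, self.src, self._polys, self._radii)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def _poly2_design(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])


def _lwm_fit(src: np.ndarray, dst: np.ndarray, k: int):
    """Per-control-point quadratic fits and influence radii."""
    n = len(src)
    k = min(k, n)
    polys = np.empty((n, 6, 2))
    radii = np.empty(n)
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        nbr = np.argsort(d2[i])[:k]
        A = _poly2_design(src[nbr])
        coef, *_ = np.linalg.lstsq(A, dst[nbr], rcond=None)
        polys[i] = coef
        radii[i] = np.sqrt(d2[i][nbr[-1]])
    return polys, radii


def _lwm_eval(pts: np.ndarray, src: np.ndarray, polys: np.ndarray, radii: np.ndarray) -> np.ndarray:
    out = np.empty_like(pts)
    for j, pt in enumerate(pts):
        r = np.sqrt(np.sum((src - pt) ** 2, axis=1)) / radii
        w = np.where(r < 1.0, 1.0 - 3.0 * r**2 + 2.0 * r**3, 0.0)
        if w.sum() == 0.0:  # outside every influence region: nearest fit
            w[np.argmin(r)] = 1.0
        pred = _poly2_design(pt[None, :])[0] @ polys  # (n_ctrl, 2)
        out[j] = (w[:, None] * pred).sum(axis=0) / w.sum()
    return out


def build_warp(beads_a, beads_b, kind: str = "affine", n_neighbors: int = 12) -> WarpModel:
    """Estimate the channel-B -> channel-A warp from matched bead centroids.

    ``beads_a`` / ``beads_b`` are (n, 2) arrays of the same beads localised
    in each channel.  Leave-one-out residuals quantify the registration
    error at the control points.
    """
    dst = np.asarray(beads_a, dtype=float).reshape(-1, 2)
    src = np.asarray(beads_b, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("control point sets must have matching shapes")
    n = len(src)
    if kind == "affine":
        if n < 3:
            raise ValueError("affine warp needs at least 3 control points")
        model = _estimate_affine(src, dst)
        warp = WarpModel(kind, src, dst, _affine=model)
    elif kind == "lwm":
        if n < 6:
            raise ValueError("local weighted mean warp needs at least 6 control points")
        polys, radii = _lwm_fit(src, dst, n_neighbors)
        warp = WarpModel(kind, src, dst, n_neighbors=n_neighbors, _polys=polys, _radii=radii)
    else:
        raise ValueError(f"unknown warp type {kind!r}")
    warp.residuals = _loo_residuals(src, dst, kind, n_neighbors)
    return warp


def _estimate_affine(src, dst) -> AffineTransform:
    try:
        model = AffineTransform.from_estimate(src, dst)
        ok = bool(model)
    except AttributeError:  # scikit-image < 0.26
        model = AffineTransform()
        ok = model.estimate(src, dst)
    if not ok or not np.all(np.isfinite(model.params)):
        raise ValueError("degenerate (collinear) control points for affine warp")
    spread = src - src.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * max(1.0, np.abs(spread).max())) < 2:
        raise ValueError("degenerate (collinear) control points for affine warp")
    return model


def _loo_residuals(src, dst, kind, k) -> np.ndarray:
    n = len(src)
    res = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            if kind == "affine":
                model = _estimate_affine(src[keep], dst[keep])
                pred = model(src[i : i + 1])[0]
            else:
                polys, radii = _lwm_fit(src[keep], dst[keep], min(k, n - 1))
                pred = _lwm_eval(src[i : i + 1], src[keep], polys, radii)[0]
            res[i] = np.hypot(*(pred - dst[i]))
        except ValueError:
            res[i] = np.nan
    return res


# ---------------------------------------------------------------------------
# Orientation / resampling helpers


def orient_to_symmetry_axis(avg: AverageTrajectory, center: bool = True):
    """Rotate an average trajectory so the invagination axis is +X.

    The axis is the principal direction of the fluorescence-weighted spread
    of the centroid positions, signed so the net (late-minus-early) motion
    points along +X.  With ``center=True`` the trajectory is additionally
    translated so its fluorescence-weighted centre of mass is the origin.
    Returns ``(oriented_average, transform)`` with ``transform`` the applied
    :class:`RigidTransform`.
    """
    w = np.clip(avg.f, 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(avg.f)
    pts = avg.xy
    mu = (w[:, None] * pts).sum(axis=0) / w.sum()
    d = pts - mu
    cov = (w[:, None] * d).T @ d / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    half = len(pts) // 2
    wl, we = w[half:], w[:half]
    late = (wl[:, None] * pts[half:]).sum(axis=0) / max(wl.sum(), 1e-300)
    early = (we[:, None] * pts[:half]).sum(axis=0) / max(we.sum(), 1e-300)
    if np.dot(late - early, axis) < 0:
        axis = -axis
    theta = -float(np.arctan2(axis[1], axis[0]))
    rot = RigidTransform(theta, 0.0, 0.0)
    x, y = rot.apply(avg.x, avg.y)
    if center:
        cx = float((w * x).sum() / w.sum())
        cy = float((w * y).sum() / w.sum())
        x, y = x - cx, y - cy
        rot = RigidTransform(theta, -cx, -cy)
    return avg.replace(x=x, y=y), rot


def resample_to_grid(traj: Trajectory, t0: float, dt: float, window: int = 3) -> Trajectory:
    """Smooth with a short moving average and cubic-spline onto a dt grid.

    The output grid is phase-locked to ``t0`` (a time stamp of the average
    trajectory) so that integer lags relate pair indices to average indices.
    If the trajectory is already on that grid and ``window <= 1`` it is
    returned unchanged.
    """
    offset = (traj.t[0] - t0) / dt
    on_grid = abs(traj.dt - dt) < 1e-9 and abs(offset - round(offset)) < 1e-6
    if on_grid and window <= 1:
        return traj
    work = traj
    if window > 1 and len(traj) >= window:
        from .trajectory import CohortConfig, smooth_trajectory

        work = smooth_trajectory(traj, CohortConfig(smoothing="moving_average", window=window))
    if on_grid:
        return work
    k0 = int(np.ceil((work.t[0] - t0) / dt - 1e-9))
    k1 = int(np.floor((work.t[-1] - t0) / dt + 1e-9))
    if k1 - k0 + 1 < 2:
        raise AlignmentError(f"trajectory {traj.id!r} spans fewer than 2 grid points")
    tt = t0 + np.arange(k0, k1 + 1) * dt
    out = {}
    for name in ("x", "y", "f"):
        out[name] = CubicSpline(work.t, getattr(work, name))(tt)
    out["f"] = np.clip(out["f"], 0.0, None)
    return traj.replace(t=tt, **out)


# ---------------------------------------------------------------------------
# Pair alignment against the averages


def _fluorescence_lag(pf: np.ndarray, Pf: np.ndarray, min_overlap: int) -> int:
    """Lag maximising sum_i p^f_{i+tau} P^f_i; ties prefer the smallest |tau|."""
    cc = np.correlate(pf, Pf, "full")
    lags = np.arange(-(len(Pf) - 1), len(pf))
    overlap = np.minimum(len(Pf), len(pf) - lags) - np.maximum(0, -lags)
    ok = overlap >= min_overlap
    if not np.any(ok):
        raise AlignmentError("no lag with sufficient fluorescence overlap")
    score = np.where(ok, cc, -np.inf)
    order = np.lexsort((lags, np.abs(lags), -score))
    return int(lags[order[0]])


def _fit_track_to_average(
    track: Trajectory,
    avg: AverageTrajectory,
    min_overlap: int,
    invagination_only: bool,
    weight_cap_quantile: float,
) -> tuple[int, RigidTransform]:
    tau = _fluorescence_lag(track.f, avg.f, min_overlap)
    i0 = max(0, -tau)
    i1 = min(len(avg), len(track) - tau)
    if i1 - i0 < 2:
        raise AlignmentError("fewer than 2 overlapping points after temporal alignment")
    idx = np.arange(i0, i1)
    if invagination_only:
        idx = idx[idx <= avg.peak_index()]
        if len(idx) < 2:
            raise AlignmentError("no points before the fluorescence peak overlap")
    denom = avg.dx[idx] * avg.dy[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = avg.f[idx] * track.f[idx + tau] / denom
    bad = ~np.isfinite(w)
    if np.any(bad) or np.any(denom <= 0):
        cap = np.nanpercentile(np.where(bad, np.nan, w), 99.0)
        if not np.isfinite(cap) or cap <= 0:
            cap = 1.0
        w = np.where(bad, cap, np.minimum(w, cap))
        log.info("capped %d weight(s) with vanishing SEM product", int(bad.sum()))
    if w.sum() <= 0:
        raise AlignmentError("zero fluorescence overlap")
    T = fit_rigid_weighted(
        np.column_stack([track.x[idx + tau], track.y[idx + tau]]),
        np.column_stack([avg.x[idx], avg.y[idx]]),
        w,
    )
    return tau, T


def pair_lag_and_fit(
    pair: TrajectoryPair,
    P: AverageTrajectory,
    R: AverageTrajectory,
    min_overlap: int = 5,
    invagination_only_reference: bool = False,
    smoothing_window: int = 3,
    resample: bool = True,
    weight_cap_quantile: float = 99.0,
) -> PairTransforms:
    """Align one two-color pair to the two average trajectories.

    Temporal lags maximise the fluorescence cross-correlation; spatial fits
    minimise the weighted squared residual with weights
    ``P^f_i p^f_{i+tau} / (dx_i dy_i)``.  The averages must already be
    oriented to their symmetry axis (and ``P`` centred) — see
    :func:`orient_to_symmetry_axis`.
    """
    p, r = pair.target, pair.reference
    if resample:
        p = resample_to_grid(p, float(P.t[0]), P.dt, smoothing_window)
        r = resample_to_grid(r, float(R.t[0]), R.dt, smoothing_window)
    tau_p, T_p = _fit_track_to_average(p, P, min_overlap, False, weight_cap_quantile)
    tau_r, T_r = _fit_track_to_average(
        r, R, min_overlap, invagination_only_reference, weight_cap_quantile
    )
    return PairTransforms(tau_p=tau_p, tau_r=tau_r, T_p=T_p, T_r=T_r)


def _median_and_se(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, MAD_TO_SD * mad / np.sqrt(len(values))


def aggregate_transforms(
    per_pair,
    dt: float,
    small_angle_threshold: float = 0.1,
) -> TransformEstimate:
    """Combine per-pair transforms into the median/MAD estimate of P -> R.

    For each pair the estimate of the transform aligning ``P`` to ``R`` is
    the exact composition ``T_r (T_p)^{-1}``; its components are aggregated
    by medians and the uncertainties are ``1.4826 x MAD / sqrt(M)``.  The
    rotation median ``median(T_r^theta - T_p^theta)`` is only meaningful
    when the two per-pair rotations nearly cancel; a warning is issued when
    the median exceeds ``small_angle_threshold`` (radians).
    """
    per_pair = list(per_pair)
    m = len(per_pair)
    if m == 0:
        raise AlignmentError("no pair transforms to aggregate")
    trx = np.array([pt.T_r.tx for pt in per_pair])
    try_ = np.array([pt.T_r.ty for pt in per_pair])
    tpx = np.array([pt.T_p.tx for pt in per_pair])
    tpy = np.array([pt.T_p.ty for pt in per_pair])
    dth = np.array([pt.T_r.theta - pt.T_p.theta for pt in per_pair])
    dth = np.arctan2(np.sin(dth), np.cos(dth))  # wrap to (-pi, pi]
    taus = np.array([pt.tau_r - pt.tau_p for pt in per_pair], dtype=float)

    tx_vals = trx - np.cos(dth) * tpx + np.sin(dth) * tpy
    ty_vals = try_ - np.sin(dth) * tpx - np.cos(dth) * tpy

    tau, dtau = _median_and_se(taus)
    theta, dtheta = _median_and_se(dth)
    tx, dtx = _median_and_se(tx_vals)
    ty, dty = _median_and_se(ty_vals)
    if abs(theta) > small_angle_threshold:
        warnings.warn(
            f"median rotation {theta:.3f} rad exceeds the small-angle threshold "
            f"({small_angle_threshold} rad); the translation composition assumes "
            "T_r^theta ~ T_p^theta",
            stacklevel=2,
        )
    return TransformEstimate(
        tau=tau * dt,
        tx=tx,
        ty=ty,
        theta=theta,
        dtau=dtau * dt,
        dtx=dtx,
        dty=dty,
        dtheta=dtheta,
        m=m,
    )


def apply_alignment(P: AverageTrajectory, est: TransformEstimate) -> AlignedTrajectory:
    """Transform the target average into the reference frame, propagating errors.

    Positional standard errors combine the averaging SEM, the rotation
    uncertainty (scaled by the lever arm of each point) and the translation
    uncertainty in quadrature:

        z_x = sqrt(dx^2 + (P_y dtheta)^2 + dtx^2)
        z_y = sqrt(dy^2 + (P_x dtheta)^2 + dty^2)

    The time axis is shifted by the median lag ``tau`` (P's clock mapped to
    the reference clock).
    """
    x, y = est.transform.apply(P.x, P.y)
    dx = np.nan_to_num(P.dx, nan=0.0)
    dy = np.nan_to_num(P.dy, nan=0.0)
    zx = np.sqrt(dx**2 + (P.y * est.dtheta) ** 2 + est.dtx**2)
    zy = np.sqrt(dy**2 + (P.x * est.dtheta) ** 2 + est.dty**2)
    return AlignedTrajectory(
        t=P.t - est.tau,
        x=x,
        y=y,
        f=P.f.copy(),
        zx=zx,
        zy=zy,
        zf=P.df.copy(),
        dtau=est.dtau,
    )


# ---------------------------------------------------------------------------
# Non-motile protein averaging


def average_nonmotile(
    pairs,
    R: AverageTrajectory,
    min_overlap: int = 5,
    smoothing_window: int = 3,
    resample: bool = True,
    invagination_only_reference: bool = False,
) -> AverageTrajectory:
    """Average target trajectories via their paired reference alignments.

    Proteins without directed motion (e.g. Myo5, Las17) cannot be aligned
    through their own average trajectory; instead each pair's reference
    track is aligned to the reference average and the resulting rotation,
    translation and lag are applied to the paired target track.  The
    transformed targets are then averaged per time index.
    """
    used = 0
    grids = []
    for pair in pairs:
        p, r = pair.target, pair.reference
        if resample:
            try:
                p = resample_to_grid(p, float(R.t[0]), R.dt, smoothing_window)
                r = resample_to_grid(r, float(R.t[0]), R.dt, smoothing_window)
            except AlignmentError as err:
                log.warning("pair %r excluded: %s", pair.acquisition_id, err)
                continue
        try:
            tau_r, T_r = _fit_track_to_average(
                r, R, min_overlap, invagination_only_reference, 99.0
            )
        except AlignmentError as err:
            log.warning("pair %r excluded: %s", pair.acquisition_id, err)
            continue
        gx, gy = T_r.apply(p.x, p.y)
        idx = np.arange(len(p)) - tau_r  # reference-frame time index
        grids.append((idx, gx, gy, p.f))
        used += 1
    if used == 0:
        raise AlignmentError("no pair could be aligned to the reference average")
    lo = min(int(g[0][0]) for g in grids)
    hi = max(int(g[0][-1]) for g in grids) + 1
    width = hi - lo
    sums = {k: np.zeros(width) for k in ("x", "y", "f", "xx", "yy", "ff")}
    counts = np.zeros(width, dtype=int)
    for idx, gx, gy, f in grids:
        sl = slice(int(idx[0]) - lo, int(idx[-1]) - lo + 1)
        sums["x"][sl] += gx
        sums["y"][sl] += gy
        sums["f"][sl] += f
        sums["xx"][sl] += gx**2
        sums["yy"][sl] += gy**2
        sums["ff"][sl] += f**2
        counts[sl] += 1
    keep = np.nonzero(counts >= 1)[0]
    first, last = keep[0], keep[-1] + 1
    cnt = counts[first:last].astype(float)

    def mean_sem(key):
        s = sums[key][first:last]
        s2 = sums[{"x": "xx", "y": "yy", "f": "ff"}[key]][first:last]
        mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (s2 - cnt * mean**2) / (cnt - 1)
            sem = np.sqrt(np.maximum(var, 0.0) / cnt)
        sem[cnt < 2] = np.nan
        return mean, sem

    mx, sx = mean_sem("x")
    my, sy = mean_sem("y")
    mf, sf = mean_sem("f")
    t = (np.arange(first, last) + lo) * R.dt + float(R.t[0])
    cnt_int = np.maximum(cnt.astype(int), 1)
    return AverageTrajectory(t=t, x=mx, y=my, f=mf, dx=sx, dy=sy, df=sf, n=cnt_int)
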