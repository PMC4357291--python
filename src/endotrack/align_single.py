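"""Pairwise weighted rigid+lag alignment and all-pairs cohort averaging.

Two patch trajectories of the same protein are related by an unknown planar
isometry (the patches sit at random positions and orientations on the cell
surface) and an unknown integer temporal lag (the events start at random
times).  The best alignment of ``p`` onto ``q`` minimises the
fluorescence-weighted mean squared residual

    cost(T, tau) = sum_i w_i |q_{i+tau} - T(p_i)|^2 / sum_i w_i,
    w_i = q_{i+tau}^f * p_i^f,

over rotations+translations ``T`` and lags ``tau``.  For each lag the
optimal ``T`` is the closed-form weighted 2D Procrustes solution; weighting
by the product of fluorescence intensities concentrates the fit on the
bright, well-localised part of the event and doubles as a temporal
cross-correlation that pins down the lag.

``align_and_average`` aligns every trajectory of a cohort to every other
(n(n-1) pairwise alignments), combines them into one per-trajectory
transform into a common frame, and averages per time index into an
:class:`~endotrack.trajectory.AverageTrajectory` with per-point SEMs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory import AverageTrajectory, CohortConfig, Trajectory
from .transforms import RigidTransform

__all__ = [
    "PairAlignment",
    "AlignmentError",
    "fit_rigid_weighted",
    "best_pair_alignment",
    "align_and_average",
]

log = logging.getLogger(__name__)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairAlignment:
    """Result of aligning one trajectory to another.

    ``transform`` maps the source ``p`` toward the target ``q``; a point of
    ``p`` at index ``i`` corresponds to ``q`` at index ``i + tau``.
    """

    transform: RigidTransform
    tau: int
    cost: float  # weighted mean squared residual, nm^2
    overlap: int  # number of overlapping frames


def fit_rigid_weighted(source, target, weights=None) -> RigidTransform:
    """Closed-form weighted least-squares rotation+translation.

    Minimises ``sum w_i |target_i - T(source_i)|^2 / sum w_i`` over planar
    isometries.  A single point pair (or collinear degeneracy of the
    cross-moments) yields a translation-only result with theta = 0.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 2)
    dst = np.asarray(target, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) == 0:
        raise AlignmentError("source and target must be non-empty point sets of equal size")
    w = np.ones(len(src)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise AlignmentError("weights must be non-negative")
    W = w.sum()
    if W <= 0:
        raise AlignmentError("all weights are zero")
    mp = (w[:, None] * src).sum(axis=0) / W
    mq = (w[:, None] * dst).sum(axis=0) / W
    ps = src - mp
    qs = dst - mq
    sxx = float(np.sum(w * (ps[:, 0] * qs[:, 0] + ps[:, 1] * qs[:, 1])))
    sxy = float(np.sum(w * (ps[:, 0] * qs[:, 1] - ps[:, 1] * qs[:, 0])))
    theta = 0.0 if sxx == 0.0 and sxy == 0.0 else float(np.arctan2(sxy, sxx))
    c, s = np.cos(theta), np.sin(theta)
    tx = mq[0] - (c * mp[0] - s * mp[1])
    ty = mq[1] - (s * mp[0] + c * mp[1])
    return RigidTransform(theta, float(tx), float(ty))


def _lag_moments(p: Trajectory, q: Trajectory):
    """All lag-indexed weighted moments needed for the rigid fit, via correlations.

    With weights w_i = p^f_i q^f_{i+tau} every moment factorises into a
    cross-correlation of per-channel products, so the whole lag sweep costs
    a handful of O(N^2) correlations instead of a per-lag Procrustes fit.
    Returns (lags, moments dict, overlap counts).
    """
    pf, qf = p.f, q.f
    na, nb = len(pf), len(qf)

    def corr(b_arr, a_arr):
        # index [nb-1+tau] not valid here; np.correlate(b, a, "full")[k] with
        # k = len(a)-1+tau gives sum_i b_{i+tau} a_i for tau in [-(na-1), nb-1]
        return np.correlate(b_arr, a_arr, "full")

    pa = {"1": pf, "x": pf * p.x, "y": pf * p.y, "r2": pf * (p.x**2 + p.y**2)}
    qa = {"1": qf, "x": qf * q.x, "y": qf * q.y, "r2": qf * (q.x**2 + q.y**2)}
    m = {
        "W": corr(qa["1"], pa["1"]),
        "px": corr(qa["1"], pa["x"]),
        "py": corr(qa["1"], pa["y"]),
        "qx": corr(qa["x"], pa["1"]),
        "qy": corr(qa["y"], pa["1"]),
        "xx": corr(qa["x"], pa["x"]) + corr(qa["y"], pa["y"]),
        "xy": corr(qa["y"], pa["x"]) - corr(qa["x"], pa["y"]),
        "pp": corr(qa["1"], pa["r2"]),
        "qq": corr(qa["r2"], pa["1"]),
    }
    lags = np.arange(-(na - 1), nb)
    overlap = np.minimum(na, nb - lags) - np.maximum(0, -lags)
    return lags, m, overlap


def best_pair_alignment(
    p: Trajectory,
    q: Trajectory,
    lag_range: tuple[int, int] | None = None,
    min_overlap: int = 5,
    p_peak: int | None = None,
    q_peak: int | None = None,
) -> PairAlignment:
    """Best rigid transform and integer lag aligning ``p`` onto ``q``.

    ``lag_range`` restricts the searched lags (inclusive bounds); by default
    every lag with at least ``min_overlap`` overlapping frames is tried.
    ``p_peak`` / ``q_peak`` truncate the contributing points at the given
    index (invagination-only costing: frames past the fluorescence peak get
    zero weight).  Ties in cost prefer the smallest ``|tau|``, then the
    smaller ``tau``.
    """
    if abs(p.dt - q.dt) > 1e-9:
        raise AlignmentError("trajectories must share the sampling interval")
    if p_peak is not None or q_peak is not None:
        p = _truncate_weights(p, p_peak)
        q = _truncate_weights(q, q_peak)
    lags, m, overlap = _lag_moments(p, q)
    ok = (overlap >= max(min_overlap, 1)) & (m["W"] > 0)
    if lag_range is not None:
        ok &= (lags >= lag_range[0]) & (lags <= lag_range[1])
    if not np.any(ok):
        raise AlignmentError(
            f"no admissible lag (max achievable overlap {int(overlap.max(initial=0))}, "
            f"minimum required {min_overlap})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        W = m["W"]
        sxx = m["xx"] - (m["px"] * m["qx"] + m["py"] * m["qy"]) / W
        sxy = m["xy"] - (m["px"] * m["qy"] - m["py"] * m["qx"]) / W
        cross = np.hypot(sxx, sxy)
        cost = (
            m["pp"]
            - (m["px"] ** 2 + m["py"] ** 2) / W
            + m["qq"]
            - (m["qx"] ** 2 + m["qy"] ** 2) / W
            - 2.0 * cross
        ) / W
    cost = np.where(ok, cost, np.inf)
    cost = np.maximum(cost, 0.0)  # guard against round-off below zero
    # tie-break: smallest |tau|, then smaller tau
    order = np.lexsort((lags, np.abs(lags), cost))
    best = order[0]
    tau = int(lags[best])
    theta = 0.0 if (sxx[best] == 0.0 and sxy[best] == 0.0) else float(np.arctan2(sxy[best], sxx[best]))
    c, s = np.cos(theta), np.sin(theta)
    mpx, mpy = m["px"][best] / W[best], m["py"][best] / W[best]
    mqx, mqy = m["qx"][best] / W[best], m["qy"][best] / W[best]
    transform = RigidTransform(
        theta,
        float(mqx - (c * mpx - s * mpy)),
        float(mqy - (s * mpx + c * mpy)),
    )
    return PairAlignment(transform, tau, float(cost[best]), int(overlap[best]))


def _truncate_weights(traj: Trajectory, peak: int | None) -> Trajectory:
    if peak is None:
        return traj
    f = traj.f.copy()
    f[peak + 1 :] = 0.0
    return traj.replace(f=f)


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def align_and_average(
    cohort,
    cfg: CohortConfig | None = None,
    min_overlap: int = 5,
    lag_range: tuple[int, int] | None = None,
    center: bool = True,
) -> AverageTrajectory:
    """All-pairs alignment of a cohort and per-timepoint averaging.

    Every trajectory serves once as the reference for all others (n(n-1)
    pairwise alignments).  The common frame is anchored at the first
    trajectory; each trajectory's transform into that frame is the average,
    over all references, of the reference's own frame transform composed
    with the pairwise transform (rotations via the circular mean, lags via
    the median).  Aligned trajectories are then averaged per time index.

    With ``center=True`` (default) the result is translated so its
    fluorescence-weighted centre of mass sits at the origin, which removes
    the arbitrary anchor offset; disable it to keep exact equivariance under
    a global isometry of the whole cohort.
    """
    cohort = list(cohort)
    n = len(cohort)
    if n < 2:
        raise AlignmentError("need at least 2 trajectories")
    cfg = cfg or CohortConfig()
    peaks = [tr.peak_index() if cfg.invagination_only else None for tr in cohort]
    dt = cohort[0].dt

    # pairwise alignments A[j][k]: trajectory j aligned onto trajectory k
    pair: dict[tuple[int, int], PairAlignment] = {}
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            try:
                pair[(j, k)] = best_pair_alignment(
                    cohort[j], cohort[k], lag_range, min_overlap, peaks[j], peaks[k]
                )
            except AlignmentError as err:
                log.warning("pair (%s, %s) excluded: %s", cohort[j].id, cohort[k].id, err)

    # frame transforms: anchor = trajectory 0
    frame_T = [RigidTransform.identity()] + [None] * (n - 1)
    frame_lag = [0] + [None] * (n - 1)
    for k in range(1, n):
        al = pair.get((k, 0))
        if al is not None:
            frame_T[k] = al.transform
            frame_lag[k] = al.tau

    # per-trajectory averaged transform into the common frame
    avg_T: list[RigidTransform | None] = [None] * n
    avg_lag: list[int | None] = [None] * n
    for j in range(n):
        thetas, txs, tys, lags = [], [], [], []
        for k in range(n):
            if k == j or frame_T[k] is None:
                continue
            al = pair.get((j, k))
            if al is None:
                continue
            comp = frame_T[k].compose(al.transform)
            thetas.append(comp.theta)
            txs.append(comp.tx)
            tys.append(comp.ty)
            lags.append(frame_lag[k] + al.tau)
        if j == 0:
            thetas.append(0.0)
            txs.append(0.0)
            tys.append(0.0)
            lags.append(0)
        if not thetas:
            log.warning("trajectory %s unalignable, dropped from the average", cohort[j].id)
            continue
        avg_T[j] = RigidTransform(_circular_mean(np.array(thetas)), float(np.mean(txs)), float(np.mean(tys)))
        avg_lag[j] = int(round(float(np.median(lags))))

    used = [j for j in range(n) if avg_T[j] is not None]
    if len(used) < 2:
        raise AlignmentError("fewer than 2 usable trajectories after pairwise alignment")

    # accumulate on the common integer time grid
    lo = min(avg_lag[j] for j in used)
    hi = max(avg_lag[j] + len(cohort[j]) for j in used)
    width = hi - lo
    sums = {k: np.zeros(width) for k in ("x", "y", "f", "xx", "yy", "ff")}
    counts = np.zeros(width, dtype=int)
    for j in used:
        tr = cohort[j]
        gx, gy = avg_T[j].apply(tr.x, tr.y)
        start = avg_lag[j] - lo
        sl = slice(start, start + len(tr))
        sums["x"][sl] += gx
        sums["y"][sl] += gy
        sums["f"][sl] += tr.f
        sums["xx"][sl] += gx**2
        sums["yy"][sl] += gy**2
        sums["ff"][sl] += tr.f**2
        counts[sl] += 1

    keep = counts >= 1
    idx = np.nonzero(keep)[0]
    first, last = idx[0], idx[-1] + 1
    cnt = counts[first:last].astype(float)
    if np.any(cnt < 1):
        # non-contiguous coverage: keep the widest contiguous block
        warnings.warn("non-contiguous time coverage; truncating to the densest block")
        inside = np.nonzero(counts[first:last] < 1)[0]
        last = first + inside[0]
        cnt = counts[first:last].astype(float)

    def mean_sem(key):
        s = sums[key][first:last]
        s2 = sums[{"x": "xx", "y": "yy", "f": "ff"}[key]][first:last]
        mean = s / cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (s2 - cnt * mean**2) / (cnt - 1)
            sem = np.sqrt(np.maximum(var, 0.0) / cnt)
        sem[cnt < 2] = np.nan
        return mean, sem

    mx, sx = mean_sem("x")
    my, sy = mean_sem("y")
    mf, sf = mean_sem("f")
    if center:
        wsum = mf.sum()
        if wsum > 0:
            mx = mx - float((mf * mx).sum() / wsum)
            my = my - float((mf * my).sum() / wsum)
    t = (np.arange(first, last) + lo) * dt + cohort[0].t[0]
    return AverageTrajectory(t=t, x=mx, y=my, f=mf, dx=sx, dy=sy, df=sf, n=cnt.astype(int))
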