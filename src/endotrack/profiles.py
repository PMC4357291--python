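"""Axisymmetric membrane invagination profiles.

A profile is a polyline of (axial depth ``z``, radius ``rho``) vertices in
nm describing the surface of revolution of the invaginated membrane, from
the flat base (z = 0) to the tip.  Surface integrals over arclength bands
are evaluated exactly for the piecewise-linear polyline (the integrand
``2 pi rho`` is linear per segment, ``2 pi rho z`` quadratic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MembraneProfile", "read_profiles", "write_profiles", "synthetic_profile_series"]


@dataclass
class MembraneProfile:
    """Axisymmetric invagination shape at one time point.

    ``z`` runs from the flat-membrane base (0) toward the tip and must be
    non-decreasing along the polyline; ``rho`` is the radius of revolution.
    ``time`` (s) is optional and used by the time-registration machinery.
    """

    z: np.ndarray
    rho: np.ndarray
    time: float | None = None
    id: object = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.rho.shape or len(self.z) < 2:
            raise ValueError("profile needs matching 1D z and rho arrays with >= 2 vertices")
        if np.any(np.diff(self.z) < 0):
            raise ValueError("z must be non-decreasing from base to tip")
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")

    def __len__(self):
        return len(self.z)

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength at each vertex, from the base."""
        return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(self.z), np.diff(self.rho)))])

    @property
    def total_arclength(self) -> float:
        return float(self.arclength[-1])

    @property
    def depth(self) -> float:
        return float(self.z[-1] - self.z[0])

    def total_area(self) -> float:
        return self.band_area(0.0, self.total_arclength)

    def _segment_integrals(self, s0: float, s1: float):
        """Exact per-segment integrals of 2*pi*rho and 2*pi*rho*z over [s0, s1]."""
        s = self.arclength
        if s0 < -1e-9 or s1 > s[-1] + 1e-9 or s0 > s1 + 1e-9:
            raise ValueError("arclength interval outside the profile")
        s0 = max(s0, 0.0)
        s1 = min(s1, float(s[-1]))
        area = 0.0
        moment = 0.0
        for k in range(len(s) - 1):
            a, b = s[k], s[k + 1]
            lo, hi = max(a, s0), min(b, s1)
            if hi <= lo or b == a:
                continue

            def interp(v, at):
                return v[k] + (v[k + 1] - v[k]) * (at - a) / (b - a)

            r_lo, r_hi = interp(self.rho, lo), interp(self.rho, hi)
            z_lo, z_hi = interp(self.z, lo), interp(self.z, hi)
            h = hi - lo
            area += np.pi * (r_lo + r_hi) * h
            # Simpson: exact for the quadratic integrand rho(s) * z(s)
            r_mid = 0.5 * (r_lo + r_hi)
            z_mid = 0.5 * (z_lo + z_hi)
            moment += 2.0 * np.pi * h / 6.0 * (r_lo * z_lo + 4.0 * r_mid * z_mid + r_hi * z_hi)
        return area, moment

    def band_area(self, s0: float, s1: float) -> float:
        """Membrane area (nm^2) of the surface of revolution over [s0, s1]."""
        return self._segment_integrals(s0, s1)[0]

    def band_com(self, s0: float, s1: float) -> float:
        """Surface-area-weighted mean axial position z of the band (nm)."""
        area, moment = self._segment_integrals(s0, s1)
        if area <= 0:
            # zero-radius band (e.g. a degenerate apex): fall back to midpoint z
            s = self.arclength
            zmid = np.interp(0.5 * (s0 + s1), s, self.z)
            return float(zmid)
        return float(moment / area)

    def resample(self, n: int) -> "MembraneProfile":
        """Reparameterize to ``n`` vertices uniform in arclength fraction."""
        s = self.arclength
        frac = s / s[-1] if s[-1] > 0 else np.linspace(0, 1, len(s))
        grid = np.linspace(0.0, 1.0, n)
        return MembraneProfile(
            z=np.interp(grid, frac, self.z),
            rho=np.interp(grid, frac, self.rho),
            time=self.time,
            id=self.id,
        )


def read_profiles(path, sep: str | None = None) -> list[MembraneProfile]:
    """Read profiles from a table with columns profile_id, z, rho [, time]."""
    from .trajectory import sniff_delimited
    df = sniff_delimited(path, sep)
    missing = {"profile_id", "z", "rho"} - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("profile_id", sort=False):
        time = float(grp["time"].iloc[0]) if "time" in grp.columns else None
        out.append(
            MembraneProfile(
                z=grp["z"].to_numpy(dtype=float),
                rho=grp["rho"].to_numpy(dtype=float),
                time=time,
                id=pid,
            )
        )
    return out


def write_profiles(profiles, path, sep: str = "\t") -> None:
    frames = []
    for prof in profiles:
        frame = pd.DataFrame({"profile_id": prof.id, "z": prof.z, "rho": prof.rho})
        if prof.time is not None:
            frame["time"] = prof.time
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def synthetic_profile_series(
    n_profiles: int = 5,
    max_depth: float = 120.0,
    tube_radius: float = 15.0,
    tip_radius: float = 20.0,
    base_radius: float = 60.0,
    vertex_spacing: float = 1.0,
    times=None,
) -> list[MembraneProfile]:
    """Plausible invagination shapes: flat -> dome -> tube with a wider tip.

    A stand-in generator for time-resolved membrane profiles (the real
    shapes come from correlative light and electron microscopy and are
    supplied by the user); synthetic, for tests and examples.  Depth grows
    linearly across the series; shallow shapes are spherical-cap domes,
    deeper ones a cylindrical tube capped by a hemispherical tip.
    """
    profiles = []
    depths = np.linspace(0.0, max_depth, n_profiles)
    for k, depth in enumerate(depths):
        if depth <= 1e-9:
            z = np.array([0.0, 0.0])
            rho = np.array([base_radius, 0.0])
        elif depth <= 2 * tip_radius:
            # spherical-cap dome of the given depth
            rcap = (depth**2 + tip_radius**2) / (2 * depth) if depth < tip_radius else tip_radius
            rcap = max(rcap, depth / 2 + 1e-6)
            npts = max(int(np.ceil(depth / vertex_spacing)), 8)
            zz = np.linspace(0.0, depth, npts)
            rho = np.sqrt(np.clip(rcap**2 - (zz - (depth - rcap)) ** 2, 0.0, None))
            z = zz
        else:
            tube_len = depth - tip_radius
            npts_t = max(int(np.ceil(tube_len / vertex_spacing)), 4)
            z_tube = np.linspace(0.0, tube_len, npts_t)
            rho_tube = np.full_like(z_tube, tube_radius)
            npts_c = max(int(np.ceil(tip_radius / vertex_spacing)), 8)
            phi = np.linspace(0.0, np.pi / 2, npts_c)
            z_cap = tube_len + tip_radius * np.sin(phi)
            rho_cap = tip_radius * np.cos(phi)
            # widen the cap smoothly to tip_radius if larger than tube
            scale = tip_radius / tube_radius if tube_radius > 0 else 1.0
            rho_cap = np.maximum(rho_cap, 0.0)
            z = np.concatenate([z_tube, z_cap[1:]])
            rho = np.concatenate([rho_tube, rho_cap[1:]])
        time = None if times is None else float(times[k])
        profiles.append(MembraneProfile(z=z, rho=rho, time=time, id=k))
    return profiles
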