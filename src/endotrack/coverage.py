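"""Membrane coverage by BAR-domain (Rvs161/167) dimers.

BAR dimers are ~13 nm long and assemble on membrane tubules in spirals
spaced by 50 A, so each dimer occupies ~13 x 5 = 65 nm^2 of membrane.
Given the number of tagged molecules at the site and an axisymmetric
invagination profile, the covered region is modelled as a contiguous
arclength band whose area matches the dimer count and whose surface centre
of mass coincides with the tracked centroid position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import MembraneProfile

__all__ = [
    "PackingModel",
    "CoverageBand",
    "band_area",
    "place_coverage",
    "extrapolate_profile",
]


@dataclass(frozen=True)
class PackingModel:
    """Rectangular tiling of the membrane by BAR dimers.

    dimer_length : long axis of the dimer (nm), default 13.
    spiral_spacing : spacing of the oligomer spiral (nm), default 5 (50 A).
    molecules_per_dimer : tagged molecules per dimer.  The default 2 maps
        N molecules to N/2 dimers; set 1 if only one subunit of the
        heterodimer carries the tag and each tagged molecule marks a dimer.
    """

    dimer_length: float = 13.0
    spiral_spacing: float = 5.0
    molecules_per_dimer: float = 2.0

    def __post_init__(self):
        if min(self.dimer_length, self.spiral_spacing, self.molecules_per_dimer) <= 0:
            raise ValueError("packing parameters must be positive")

    @property
    def area_per_dimer(self) -> float:
        return self.dimer_length * self.spiral_spacing

    def dimer_count(self, n_molecules: float) -> float:
        return n_molecules / self.molecules_per_dimer

    def target_area(self, n_molecules: float) -> float:
        return self.dimer_count(n_molecules) * self.area_per_dimer


@dataclass
class CoverageBand:
    """A contiguous covered arclength band on a profile."""

    s0: float
    s1: float
    area: float
    com_z: float  # surface-weighted axial centre of mass (nm)
    dimers: float
    clipped: bool = False
    lower: "CoverageBand | None" = None  # bands for n -/+ n_err, when requested
    upper: "CoverageBand | None" = None

    @property
    def length(self) -> float:
        return self.s1 - self.s0


def band_area(profile: MembraneProfile, s0: float, s1: float) -> float:
    """Surface area (nm^2) of the band [s0, s1]; see MembraneProfile.band_area."""
    return profile.band_area(s0, s1)


def _place_single(
    profile: MembraneProfile,
    area: float,
    centroid_z: float,
    dimers: float,
    scan_step: float,
) -> CoverageBand:
    total_s = profile.total_arclength
    total_area = profile.total_area()
    if area <= 0:
        # empty band anchored at the centroid position
        s_at = float(np.interp(centroid_z, profile.z, profile.arclength))
        return CoverageBand(s0=s_at, s1=s_at, area=0.0, com_z=centroid_z, dimers=dimers)
    if area >= total_area:
        return CoverageBand(
            s0=0.0,
            s1=total_s,
            area=total_area,
            com_z=profile.band_com(0.0, total_s),
            dimers=dimers,
            clipped=True,
        )
    # dense cumulative integrals for the scan
    n_dense = max(int(np.ceil(total_s / scan_step)) + 1, 16)
    s = np.linspace(0.0, total_s, n_dense)
    sv = profile.arclength
    rho = np.interp(s, sv, profile.rho)
    z = np.interp(s, sv, profile.z)
    dA = 2 * np.pi * 0.5 * (rho[1:] + rho[:-1]) * np.diff(s)
    F = np.concatenate([[0.0], np.cumsum(dA)])
    dG = 2 * np.pi * 0.5 * (rho[1:] * z[1:] + rho[:-1] * z[:-1]) * np.diff(s)
    G = np.concatenate([[0.0], np.cumsum(dG)])
    # candidate starts: all s0 with F(s0) + area <= F(total)
    valid = F <= F[-1] - area
    starts = s[valid]
    # band end via the inverse cumulative area
    ends = np.interp(F[valid] + area, F, s)
    areas = np.interp(ends, s, F) - F[valid]
    moments = np.interp(ends, s, G) - G[valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        coms = np.where(areas > 0, moments / np.maximum(areas, 1e-300), 0.5 * (starts + ends))
    best = int(np.argmin(np.abs(coms - centroid_z)))
    s0, s1 = float(starts[best]), float(ends[best])
    return CoverageBand(
        s0=s0,
        s1=s1,
        area=profile.band_area(s0, s1),
        com_z=profile.band_com(s0, s1),
        dimers=dimers,
    )


def place_coverage(
    profile: MembraneProfile,
    n_molecules: float,
    centroid_z: float,
    packing: PackingModel | None = None,
    n_err: float | None = None,
    scan_step: float = 0.05,
) -> CoverageBand:
    """Contiguous band of the dimer-count area whose centre of mass matches
    the tracked centroid.

    ``centroid_z`` is the centroid position on the profile's axial depth
    axis.  Among all contiguous arclength bands of the target area
    (dimers x area-per-dimer, dimers = N / molecules_per_dimer), the one
    whose surface-weighted axial centre of mass is closest to the centroid
    is returned.  If the required area exceeds the profile the band is
    clipped to the full profile and flagged.  With ``n_err`` the bands for
    N -/+ n_err are attached as ``lower`` / ``upper`` coverage bounds.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    packing = packing or PackingModel()
    band = _place_single(
        profile, packing.target_area(n_molecules), centroid_z, packing.dimer_count(n_molecules), scan_step
    )
    if n_err is not None:
        n_lo = max(n_molecules - n_err, 0.0)
        n_hi = n_molecules + n_err
        band.lower = _place_single(
            profile, packing.target_area(n_lo), centroid_z, packing.dimer_count(n_lo), scan_step
        )
        band.upper = _place_single(
            profile, packing.target_area(n_hi), centroid_z, packing.dimer_count(n_hi), scan_step
        )
    return band


def extrapolate_profile(profiles, t: float, max_overshoot: float = 1.0) -> MembraneProfile:
    """Vertexwise linear inter-/extrapolation of time-registered profiles.

    Profiles are reparameterized by arclength fraction to a common vertex
    count (the maximum over inputs) and interpolated vertexwise in time.
    ``t`` may lie beyond the covered time span by at most ``max_overshoot``
    times the adjacent inter-profile interval.
    """
    profs = sorted(list(profiles), key=lambda p: p.time)
    if len(profs) < 2:
        raise ValueError("need at least 2 time-registered profiles")
    times = np.array([p.time for p in profs], dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValueError("all profiles must carry a time stamp")
    for k, prof in enumerate(profs):
        if abs(t - times[k]) < 1e-12:
            return MembraneProfile(z=prof.z.copy(), rho=prof.rho.copy(), time=t, id=prof.id)
    lo_limit = times[0] - max_overshoot * max(times[1] - times[0], 1e-12)
    hi_limit = times[-1] + max_overshoot * max(times[-1] - times[-2], 1e-12)
    if t < lo_limit - 1e-12 or t > hi_limit + 1e-12:
        raise ValueError(
            f"t = {t} is more than one inter-profile interval beyond the span "
            f"[{times[0]}, {times[-1]}]"
        )
    n = max(len(p) for p in profs)
    res = [p.resample(n) for p in profs]
    if t <= times[0]:
        i, j = 0, 1
    elif t >= times[-1]:
        i, j = len(profs) - 2, len(profs) - 1
    else:
        j = int(np.searchsorted(times, t))
        i = j - 1
    frac = (t - times[i]) / (times[j] - times[i])
    z = res[i].z + frac * (res[j].z - res[i].z)
    rho = np.clip(res[i].rho + frac * (res[j].rho - res[i].rho), 0.0, None)
    z = np.maximum.accumulate(z - z[0])  # enforce the monotone-depth invariant
    return MembraneProfile(z=z, rho=rho, time=t)
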