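"""Density profiles, coexistence densities, and critical-point fitting.

Direct-coexistence simulations place a dense slab of chromatin arrays in an
elongated periodic box.  Averaging the mass density along the long axis
(with the center of mass re-centered each frame) yields a two-plateau
profile whose plateaus are the coexistence densities at that salt.  A set
of coexistence points over salt forms the binodal; the critical point is
obtained by fitting the density gap to 3-D Ising scaling,
``(rho_h - rho_l)^3.06 = d (1 - c/c_c)``, together with the law of
rectilinear diameter, ``(rho_l + rho_h)/2 = rho_c + s (c_c - c)``.

Densities are the molar mass of chromatin per volume in g/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GRAMS_PER_LITER",
    "DensityProfile",
    "BinodalPoint",
    "CriticalFit",
    "density_profile",
    "coexistence_densities",
    "fit_critical",
    "ISING_EXPONENT",
]

#: conversion factor: (g/mol per A^3) -> g/L
GRAMS_PER_LITER = 1.0e27 / 6.02214076e23

#: 1/beta for the 3-D Ising universality class, fixed (not a fit parameter)
ISING_EXPONENT = 3.06


@dataclass
class DensityProfile:
    """Mass density along one box axis, g/L per bin."""

    bin_centers: np.ndarray
    density: np.ndarray
    axis: int = 2
    bin_width: float = 1.0

    def total_mass_per_area(self) -> float:
        """Integral of the profile (g/L * A); bookkeeping identity helper."""
        return float(np.sum(self.density) * self.bin_width)


def density_profile(traj, ff, n_bins: int = 100, axis: int = 2, equilibration: float = 0.2) -> DensityProfile:
    """COM-centered average mass density along a box axis over a trajectory.

    The first ``equilibration`` fraction of frames is discarded; every
    remaining frame is shifted so the system center of mass sits at the box
    midpoint before histogramming bead masses.
    """
    frames = traj.frames[int(equilibration * len(traj.frames)) :]
    if not frames:
        raise ValueError("empty frame range after equilibration cut")
    box = traj.box
    if box is None:
        raise ValueError("density profiles require a periodic box")
    L = float(box[axis])
    masses = ff.masses(traj.bead_class)
    edges = np.linspace(0.0, L, n_bins + 1)
    hist = np.zeros(n_bins)
    for f in frames:
        x = f.positions[:, axis]
        com = np.average(x, weights=masses)
        xc = np.mod(x - com + L / 2.0, L)
        hist += np.histogram(xc, bins=edges, weights=masses)[0]
    hist /= len(frames)
    cross_section = np.prod([box[a] for a in range(3) if a != axis])
    bin_volume = cross_section * (L / n_bins)
    rho = hist / bin_volume * GRAMS_PER_LITER
    centers = 0.5 * (edges[:-1] + edges[1:]) - L / 2.0
    return DensityProfile(bin_centers=centers, density=rho, axis=axis, bin_width=L / n_bins)


@dataclass
class BinodalPoint:
    """Coexistence densities at one salt concentration."""

    salt: float  # mM
    rho_low: float  # g/L
    rho_high: float  # g/L
    err_low: float = 0.0
    err_high: float = 0.0
    two_phase: bool = True

    def __post_init__(self):
        if self.two_phase and self.rho_high < self.rho_low:
            raise ValueError("rho_high must be >= rho_low")


def coexistence_densities(
    profile: DensityProfile,
    slab_core_fraction: float = 0.6,
    far_field_fraction: float = 0.2,
    min_contrast: float = 0.2,
) -> BinodalPoint:
    """Plateau densities of a slab profile, or a no-coexistence marker.

    The dense plateau is the mean over the central ``slab_core_fraction`` of
    the detected slab (the region above the mid-density), the dilute plateau
    the mean over the ``far_field_fraction`` of the box farthest from the
    slab center; interfacial bins are excluded by construction.  When the
    relative contrast ``(rho_h - rho_l)/(rho_h + rho_l)`` falls below
    ``min_contrast`` the profile is declared single-phase (a valid outcome,
    not an error).
    """
    z = profile.bin_centers
    rho = profile.density
    n = len(rho)
    half_level = 0.5 * (np.max(rho) + np.min(rho))
    slab = rho > half_level
    if 0 < slab.sum() < n:
        idx = np.flatnonzero(slab)
        width = idx[-1] - idx[0] + 1
        core_half = max(1, int(slab_core_fraction * width / 2))
        center = (idx[0] + idx[-1]) // 2
        core = slice(max(0, center - core_half), min(n, center + core_half + 1))
        rho_h = float(np.mean(rho[core]))
        dist = np.abs(np.arange(n) - center)
        far = np.argsort(dist)[-max(1, int(far_field_fraction * n)) :]
        rho_l = float(np.mean(rho[far]))
    else:
        rho_h = rho_l = float(np.mean(rho))
    if rho_h + rho_l <= 0 or (rho_h - rho_l) / (rho_h + rho_l) < min_contrast:
        mean = float(np.mean(rho))
        return BinodalPoint(salt=np.nan, rho_low=mean, rho_high=mean, two_phase=False)
    err_h = float(np.std(rho[core]) / np.sqrt(max(1, core.stop - core.start)))
    err_l = float(np.std(rho[far]) / np.sqrt(len(far)))
    return BinodalPoint(salt=np.nan, rho_low=rho_l, rho_high=rho_h, err_low=err_l, err_high=err_h)


@dataclass
class CriticalFit:
    """Fitted critical point and scaling parameters of a binodal."""

    c_c: float  # critical salt
    rho_c: float  # g/L
    d: float
    s: float
    errors: dict = field(default_factory=dict)
    extrapolated: bool = False


def fit_critical(points: list[BinodalPoint]) -> CriticalFit:
    """Least-squares critical-point fit of a set of two-phase binodal points.

    Solves jointly for ``(c_c, rho_c, d, s)`` in the Ising-scaling gap law
    (with the multiplicative prefactor ``d``) and the rectilinear-diameter
    law.  Parameter errors come from the Jacobian covariance at the optimum.
    Raises on fewer than three two-phase points or degenerate data.
    """
    pts = [p for p in points if p.two_phase]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 two-phase points, got {len(pts)}")
    c = np.array([p.salt for p in pts])
    gap = np.array([p.rho_high - p.rho_low for p in pts])
    mid = np.array([0.5 * (p.rho_high + p.rho_low) for p in pts])
    if np.ptp(c) == 0 or np.all(gap == gap[0]):
        raise ValueError("degenerate binodal data: no variation across salts")

    c_scale = float(np.max(c))
    cc0 = c_scale * 1.05
    d0 = float(gap.max() ** ISING_EXPONENT / max(1e-12, 1.0 - c.min() / cc0))
    s0 = float(-np.polyfit(c, mid, 1)[0])
    rho0 = float(np.mean(mid))

    def residuals(p):
        cc, rho_c, logd, s = p
        cc = abs(cc)
        arg = 1.0 - c / cc
        gap_model = np.where(arg > 0, (np.exp(logd) * np.clip(arg, 0, None)) ** (1.0 / ISING_EXPONENT), 0.0)
        r1 = gap_model - gap
        r2 = (rho_c + s * (cc - c)) - mid
        return np.concatenate([r1, r2 / max(1.0, np.mean(np.abs(mid)))])

    x0 = np.array([cc0, rho0, np.log(max(d0, 1e-12)), s0])
    res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    if not res.success and np.max(np.abs(res.fun)) > 1e-3 * max(1.0, gap.max()):
        raise ValueError(f"critical-point fit failed: {res.message}")
    cc, rho_c, logd, s = res.x
    cc = abs(cc)

    # parameter errors from the least-squares Jacobian
    dof = max(1, len(res.fun) - 4)
    chi2 = float(np.sum(res.fun**2))
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * chi2 / dof
        perr = np.sqrt(np.abs(np.diag(cov)))
    except np.linalg.LinAlgError:
        perr = np.full(4, np.nan)
    d_val = float(np.exp(logd))
    errors = {
        "c_c": float(perr[0]),
        "rho_c": float(perr[1]),
        "d": float(perr[2] * d_val),  # delta(e^x) = e^x delta(x)
        "s": float(perr[3]),
    }
    extrapolated = not (c.min() <= cc <= c.max())
    return CriticalFit(c_c=float(cc), rho_c=float(rho_c), d=d_val, s=float(s), errors=errors, extrapolated=extrapolated)
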