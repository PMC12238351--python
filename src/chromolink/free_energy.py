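"""Umbrella sampling and WHAM reconstruction of potentials of mean force.

Collective variables supported for fiber systems are the inter-fiber
center-of-mass distance and the end-to-end extension of a single fiber.
Each umbrella window applies a harmonic bias ``1/2 k (x - x0)^2`` and is
sampled with its own temperature-replica-exchange run (no exchanges between
windows); only the lowest-temperature replica contributes samples.

The WHAM solver is the standard single-temperature binned iteration: window
free energies are refined until self-consistency, after which the unbiased
density gives the PMF up to an additive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import KB

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "wham",
    "pmf_minimum",
    "profile_minimum",
    "umbrella_sample",
    "InterFiberDistanceCV",
    "EndToEndCV",
    "INTER_FIBER_PROTOCOL",
    "INTRA_FIBER_PROTOCOL",
]

#: production umbrella protocols: (n_windows, cv range A, force constant)
INTER_FIBER_PROTOCOL = {"n_windows": 16, "cv_min": 0.0, "cv_max": 600.0, "k_bias": 0.002}
INTRA_FIBER_PROTOCOL = {"n_windows": 20, "cv_min": 0.0, "cv_max": 950.0, "k_bias": 0.0005}


@dataclass
class UmbrellaWindow:
    """Biased samples from one umbrella window."""

    cv_center: float  # A
    force_constant: float  # kcal/mol/A^2
    samples: np.ndarray  # (n, 2): cv value, total potential energy
    temperature: float = 300.0  # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 2)

    @property
    def cv_values(self) -> np.ndarray:
        return self.samples[:, 0]

    def bias(self, x) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x) - self.cv_center) ** 2


@dataclass
class PMFProfile:
    """Free energy versus collective variable, defined up to a constant."""

    cv: np.ndarray
    free_energy: np.ndarray
    uncertainty: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def aligned(self, mode: str = "plateau") -> "PMFProfile":
        """Shift so the tail plateau (or the minimum) sits at zero."""
        g = self.free_energy
        finite = np.isfinite(g)
        if mode == "plateau":
            tail = np.flatnonzero(finite)[-max(1, int(0.1 * finite.sum())) :]
            shift = float(np.mean(g[tail]))
        elif mode == "min":
            shift = float(np.min(g[finite]))
        else:
            raise ValueError(f"unknown alignment {mode!r}")
        return PMFProfile(self.cv, g - shift, self.uncertainty, dict(self.meta))


def wham(
    windows: list[UmbrellaWindow],
    T: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    n_bins: int | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution over the supplied umbrella windows.

    Raises if the pooled histogram support is disconnected (non-overlapping
    windows), naming the gap.  The returned PMF is in kcal/mol on the bin
    centers of a shared grid (default bin width = range / 200).
    """
    windows = [w for w in windows if len(w.samples)]
    if not windows:
        raise ValueError("no non-empty umbrella windows")
    beta = 1.0 / (KB * T)
    allx = np.concatenate([w.cv_values for w in windows])
    lo, hi = float(np.min(allx)), float(np.max(allx))
    if hi <= lo:
        raise ValueError("degenerate collective-variable range")
    if n_bins is None:
        n_bins = 200
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.cv_values, bins=edges)[0] for w in windows])  # (W, B)
    total = counts.sum(axis=0)
    populated = total > 0

    # non-overlapping windows leave an uncovered stretch of the reaction
    # coordinate; tolerate isolated empty bins (sampling noise in tails)
    # but reject a contiguous empty run inside the populated range
    idx = np.flatnonzero(populated)
    if len(windows) > 1 and len(idx) > 1:
        runs = np.diff(idx) - 1
        max_gap_bins = max(3, n_bins // 40)
        bad = np.flatnonzero(runs > max_gap_bins)
        if bad.size:
            g0, g1 = idx[bad[0]], idx[bad[0] + 1]
            raise ValueError(
                "disconnected histogram support: no samples between "
                f"cv = {centers[g0]:.3g} and cv = {centers[g1]:.3g} A"
            )

    n_samples = counts.sum(axis=1).astype(float)  # (W,)
    bias = np.stack([w.bias(centers) for w in windows])  # (W, B)
    boltz = np.exp(-beta * bias)
    f = np.zeros(len(windows))
    for _ in range(int(max_iter)):
        denom = np.einsum("w,w,wb->b", n_samples, np.exp(beta * f), boltz)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(populated, total / denom, 0.0)
        z = boltz @ p
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        warnings.warn("WHAM did not converge within max_iter", RuntimeWarning)

    with np.errstate(divide="ignore"):
        g = np.where(populated, -np.log(np.where(populated, p, 1.0)) / beta, np.nan)
    g -= np.nanmin(g)
    return PMFProfile(centers, g, meta={"temperature": T, "f_windows": f.tolist(), "n_bins": n_bins})


def profile_minimum(x, y, tail_fraction: float = 0.1):
    """Quadratic-interpolated interior minimum of a profile.

    Returns ``(location, depth)`` with the depth measured relative to the
    large-``x`` plateau (mean over the last ``tail_fraction`` of points), or
    ``(None, 0.0)`` if the profile has no interior minimum below the plateau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return None, 0.0
    n_tail = max(1, int(tail_fraction * len(x)))
    plateau = float(np.mean(y[-n_tail:]))
    i = int(np.argmin(y))
    if i == 0 or i == len(y) - 1 or y[i] >= plateau - 1e-12:
        return None, 0.0
    # quadratic through the three points around the discrete minimum
    x0, x1, x2 = x[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:
        loc, val = float(x1), float(y1)
    else:
        loc = -b / (2 * a)
        c = y1 - a * x1**2 - b * x1
        val = a * loc**2 + b * loc + c
    return float(loc), float(val - plateau)


def pmf_minimum(profile: PMFProfile, tail_fraction: float = 0.1):
    """Location and depth of the bound-state well of a PMF.

    Depth is measured relative to the large-separation plateau; a monotone
    (unbound) profile yields ``(None, 0.0)`` rather than an error.
    """
    return profile_minimum(profile.cv, profile.free_energy, tail_fraction=tail_fraction)


class InterFiberDistanceCV:
    """Center-of-mass distance between two fibers of a system."""

    def __init__(self, fiber_a: int = 0, fiber_b: int = 1):
        self.fiber_a = fiber_a
        self.fiber_b = fiber_b

    def _masks(self, system):
        return system.fiber_id == self.fiber_a, system.fiber_id == self.fiber_b

    def value(self, system, masses) -> float:
        ma, mb = self._masks(system)
        ra = np.average(system.positions[ma], axis=0, weights=masses[ma])
        rb = np.average(system.positions[mb], axis=0, weights=masses[mb])
        return float(np.linalg.norm(ra - rb))

    def gradient(self, system, masses) -> np.ndarray:
        """d cv / d positions, shape (n_beads, 3)."""
        ma, mb = self._masks(system)
        ra = np.average(system.positions[ma], axis=0, weights=masses[ma])
        rb = np.average(system.positions[mb], axis=0, weights=masses[mb])
        d = ra - rb
        r = np.linalg.norm(d)
        u = d / r if r > 0 else np.zeros(3)
        grad = np.zeros_like(system.positions)
        grad[ma] = (masses[ma] / masses[ma].sum())[:, None] * u
        grad[mb] = -(masses[mb] / masses[mb].sum())[:, None] * u
        return grad


class EndToEndCV:
    """Distance between the first and last nucleosome core of one fiber."""

    def __init__(self, fiber: int = 0):
        self.fiber = fiber

    def _ends(self, system):
        from .model import HISTONE_CORE

        sel = np.flatnonzero((system.fiber_id == self.fiber) & (system.bead_class == HISTONE_CORE))
        return sel[0], sel[-1]

    def value(self, system, masses=None) -> float:
        i, j = self._ends(system)
        return float(np.linalg.norm(system.positions[i] - system.positions[j]))

    def gradient(self, system, masses=None) -> np.ndarray:
        i, j = self._ends(system)
        d = system.positions[i] - system.positions[j]
        r = np.linalg.norm(d)
        u = d / r if r > 0 else np.zeros(3)
        grad = np.zeros_like(system.positions)
        grad[i] = u
        grad[j] = -u
        return grad


def umbrella_windows_for(protocol: dict) -> tuple[np.ndarray, float]:
    """Window centers and force constant of a named umbrella protocol."""
    centers = np.linspace(protocol["cv_min"], protocol["cv_max"], protocol["n_windows"])
    return centers, protocol["k_bias"]


def umbrella_sample(system, cv, centers, k_bias: float, ff, config) -> list[UmbrellaWindow]:
    """Run one biased T-REMD simulation per window and collect 300 K samples.

    ``config`` is a :class:`chromolink.dynamics.SimulationConfig` whose
    ``temperatures`` may be a ladder; windows never exchange with each other.
    Empty windows (no samples) are flagged with a warning, not fatal.
    """
    from .dynamics import run_remd

    out = []
    for i, x0 in enumerate(np.atleast_1d(centers)):
        cfg = config.with_seed(config.seed + 7919 * i)
        result = run_remd(system.copy(), ff, cfg, bias=(cv, float(x0), float(k_bias)))
        traj = result.cold_trajectory
        samp = np.array([[f.meta["cv"], f.energy] for f in traj.frames if "cv" in f.meta])
        if len(samp) == 0:
            warnings.warn(f"umbrella window at {x0:g} A produced no samples", RuntimeWarning)
        out.append(UmbrellaWindow(float(x0), float(k_bias), samp.reshape(-1, 2), temperature=min(cfg.ladder())))
    return out
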