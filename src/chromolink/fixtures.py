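"""Deterministic synthetic inputs that make every analysis testable.

These generators invert the analysis contracts: idealized stacked
nucleosome pairs for the contact classifier and pair-energy scans,
binodal points drawn exactly from the critical-scaling laws, and
exact-distribution biased samples from declared 1-D potentials for WHAM
validation.  Each takes an explicit seed where randomness is involved.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .fiber import FiberState, build_fiber, initialize_conformation
from .metrics import NucleosomeFrame

__all__ = [
    "transform_fiber",
    "make_stacked_pair_fixture",
    "make_synthetic_binodal",
    "make_wham_oracle",
    "make_slab_profile_fixture",
]


def transform_fiber(state: FiberState, rotation: Rotation | None = None, translation=None, about=None) -> FiberState:
    """Rigidly rotate (about ``about``, default the first core bead) then translate."""
    new = state.copy()
    if rotation is not None:
        pivot = new.positions[new.topology.core_indices[0]] if about is None else np.asarray(about, dtype=float)
        new.positions = pivot + rotation.apply(new.positions - pivot)
        q = Rotation.from_quat(new.quats, scalar_first=True)
        new.quats = (rotation * q).as_quat(scalar_first=True)
    if translation is not None:
        new.positions = new.positions + np.asarray(translation, dtype=float)
    return new


def make_stacked_pair_fixture(geometry: str, distance: float):
    """Two mononucleosomes in an idealized relative geometry.

    ``geometry``: ``face_face`` (coaxial discs, parallel normals, separated
    along the shared axis), ``side_side`` (edge-on approach: both axes
    perpendicular to the center-center vector and to each other), or
    ``face_side`` (one disc facing the other's edge).  Returns
    ``(frame_a, frame_b, state_a, state_b)`` with the nucleosome frames
    centered on the core beads.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    state_a = _upright_mononucleosome().copy()
    core = state_a.topology.core_indices[0]

    if geometry == "face_face":
        state_b = transform_fiber(state_a, translation=np.array([0.0, 0.0, distance]))
    elif geometry == "side_side":
        # B's axis turned onto y: axes mutually perpendicular, both normal
        # to the center-center (x) direction
        state_b = transform_fiber(state_a, rotation=Rotation.from_euler("x", 90, degrees=True))
        state_b = transform_fiber(state_b, translation=np.array([distance, 0.0, 0.0]))
    elif geometry == "face_side":
        # A's face normal is turned onto the center-center (x) axis; B keeps
        # its normal on +z, perpendicular to the center-center vector
        upright = state_a
        state_a = transform_fiber(state_a, rotation=Rotation.from_euler("y", 90, degrees=True))
        state_b = transform_fiber(upright, translation=np.array([distance, 0.0, 0.0]))
    else:
        raise ValueError(f"unknown pair geometry {geometry!r}")

    na = Rotation.from_quat(state_a.quats[core], scalar_first=True).apply([0.0, 0.0, 1.0])
    nb = Rotation.from_quat(state_b.quats[core], scalar_first=True).apply([0.0, 0.0, 1.0])
    frame_a = NucleosomeFrame(state_a.positions[core], na, fiber=0, index=0)
    frame_b = NucleosomeFrame(state_b.positions[core], nb, fiber=1, index=0)
    return frame_a, frame_b, state_a, state_b


_MONO_CACHE: dict = {}


def _upright_mononucleosome() -> FiberState:
    """Extended 147-bp mononucleosome, core at the origin, face normal +z."""
    if "state" not in _MONO_CACHE:
        base = initialize_conformation(build_fiber(1, [], (0, 0)), mode="extended")
        core = base.topology.core_indices[0]
        q_core = Rotation.from_quat(base.quats[core], scalar_first=True)
        st = transform_fiber(base, rotation=q_core.inv())
        st = transform_fiber(st, translation=-st.positions[core])
        _MONO_CACHE["state"] = st
    return _MONO_CACHE["state"]


def make_synthetic_binodal(c_c: float, rho_c: float, d: float, s: float, salts, noise: float = 0.0, seed: int = 0):
    """Binodal points generated by exact inversion of the critical scaling laws.

    For salts below ``c_c`` the density gap follows
    ``(rho_h - rho_l)^3.06 = d (1 - c/c_c)`` and the diameter the rectilinear
    law ``(rho_l + rho_h)/2 = rho_c + s (c_c - c)``; optional relative
    Gaussian noise is applied to both branches.  Salts at or above ``c_c``
    yield single-phase marker points (``rho_l == rho_h``).
    """
    from .phase import BinodalPoint

    rng = np.random.default_rng(seed)
    out = []
    for c in np.atleast_1d(salts):
        c = float(c)
        if c >= c_c:
            rho = rho_c + s * (c_c - c)
            out.append(BinodalPoint(salt=c, rho_low=rho, rho_high=rho, two_phase=False))
            continue
        gap = (d * (1.0 - c / c_c)) ** (1.0 / 3.06)
        mid = rho_c + s * (c_c - c)
        lo, hi = mid - gap / 2.0, mid + gap / 2.0
        if noise > 0:
            lo *= 1.0 + noise * rng.standard_normal()
            hi *= 1.0 + noise * rng.standard_normal()
        out.append(BinodalPoint(salt=c, rho_low=lo, rho_high=hi, err_low=noise * abs(lo), err_high=noise * abs(hi)))
    return out


def make_wham_oracle(U, windows, k_bias: float, n_samples: int, T: float = 300.0, seed: int = 0, support=None):
    """Exact-distribution biased samples from a declared 1-D potential.

    ``U`` maps x (A) to energy (kcal/mol); each window at center ``x0``
    samples ``exp(-beta (U(x) + 1/2 k (x - x0)^2))`` by rejection on the
    ``support`` interval.  Returns a list of UmbrellaWindows whose recorded
    total energy is ``U(x)`` (the unbiased part, as a sampler would log).
    """
    from .free_energy import UmbrellaWindow
    from .model import KB

    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * T)
    centers = np.atleast_1d(windows).astype(float)
    if support is None:
        pad = 3.0 * np.sqrt(1.0 / (beta * k_bias)) if k_bias > 0 else 0.0
        support = (centers.min() - pad, centers.max() + pad)
    lo, hi = support
    grid = np.linspace(lo, hi, 4001)

    out = []
    for x0 in centers:
        logmax = float(np.max(-beta * (np.asarray(U(grid)) + 0.5 * k_bias * (grid - x0) ** 2)))
        samples = np.empty(0)
        while len(samples) < n_samples:
            x = rng.uniform(lo, hi, size=4 * max(n_samples, 64))
            lw = -beta * (np.asarray(U(x)) + 0.5 * k_bias * (x - x0) ** 2) - logmax
            accept = rng.uniform(0, 1, size=len(x)) < np.exp(np.minimum(lw, 0.0))
            samples = np.concatenate([samples, x[accept]])
        samples = samples[:n_samples]
        energies = np.asarray(U(samples), dtype=float)
        out.append(UmbrellaWindow(float(x0), float(k_bias), np.stack([samples, energies], axis=1), temperature=T))
    return out


def make_slab_profile_fixture(
    rho_low: float,
    rho_high: float,
    box_z: float = 3000.0,
    slab_width: float = 900.0,
    n_bins: int = 150,
    interface_width: float = 60.0,
):
    """A synthetic two-plateau density profile with tanh interfaces (g/L)."""
    from .phase import DensityProfile

    z = (np.arange(n_bins) + 0.5) * (box_z / n_bins) - box_z / 2.0
    half = slab_width / 2.0
    shape = 0.5 * (np.tanh((z + half) / interface_width) - np.tanh((z - half) / interface_width))
    rho = rho_low + (rho_high - rho_low) * shape
    return DensityProfile(bin_centers=z, density=rho, axis=2, bin_width=box_z / n_bins)
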