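"""Rigid-body Langevin dynamics, replica exchange, and slab setups.

Every bead is a rigid body; the nucleosomal DNA beads and the histone core
of each nucleosome form one composite rigid body.  Bodies evolve under a
stochastic-splitting (BAOAB) Langevin integrator: deterministic half-kicks
and drifts around an exact Ornstein-Uhlenbeck velocity update, applied to
both translation and rotation.  Rotational inertia is treated as isotropic
(the mean principal moment), which removes gyroscopic precession terms; at
the friction used here dynamics are diffusive and this approximation only
rescales short-time rotational kinetics.

Forces: Lennard-Jones pair forces are analytic; the rigid-base-pair bonded
term uses analytic translational gradients and central finite differences
in rotation-vector coordinates for the orientational torques.

Units: A, fs, kcal/mol, g/mol.  ``ACCEL`` converts kcal/mol/A to
g/mol * A/fs^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import model
from .fiber import FiberState, FiberTopology, System
from .model import KB, ForceField

__all__ = [
    "ACCEL",
    "SimulationConfig",
    "Frame",
    "Trajectory",
    "IntegrationError",
    "run_langevin",
    "remd_accept",
    "run_remd",
    "REMDResult",
    "geometric_ladder",
    "autosize_ladder",
    "direct_coexistence_setup",
    "slab_mass_density",
]

#: kcal/mol -> g/mol * A^2/fs^2
ACCEL = 4.184e-4

_FORCE_LIMIT = 1e5  # kcal/mol/A; beyond this the configuration is unphysical


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one dynamics run (temperatures in K, salt in mM)."""

    timestep: float = 100.0  # fs
    temperatures: float | tuple = 300.0
    friction: float = 0.01  # 1/fs
    seed: int = 0
    box: tuple | None = None
    salt: float = 150.0
    n_steps: int = 1000
    output_stride: int = 100
    exchange_every: int = 100
    fix_com: bool = False

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        temps = np.atleast_1d(np.asarray(self.temperatures, dtype=float))
        if np.any(temps < 0):
            raise ValueError("temperatures must be non-negative")
        if len(temps) > 1 and np.any(np.diff(temps) < 0):
            raise ValueError("temperature ladder must be sorted ascending")

    def ladder(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.temperatures, dtype=float))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class Frame:
    step: int
    positions: np.ndarray
    quats: np.ndarray
    energy: float
    meta: dict = field(default_factory=dict)


class Trajectory:
    """Recorded frames of one run, with uniform stride."""

    def __init__(self, system: System, stride: int):
        self.frames: list[Frame] = []
        self.stride = stride
        self.box = None if system.box is None else system.box.copy()
        self.bead_class = system.bead_class
        self.fiber_id = system.fiber_id
        self.topologies = system.topologies
        self._system = system

    def record(self, step: int, positions, quats, energy: float, meta=None):
        self.frames.append(Frame(step, positions.copy(), quats.copy(), float(energy), dict(meta or {})))

    def final_system(self) -> System:
        sys = self._system.copy()
        if self.frames:
            sys.positions = self.frames[-1].positions.copy()
            sys.quats = self.frames[-1].quats.copy()
        return sys

    def fiber_com(self, ff: ForceField) -> np.ndarray:
        """(n_frames, n_fibers, 3) center-of-mass track per fiber (unwrapped)."""
        masses = ff.masses(self.bead_class)
        n_fib = len(self.topologies)
        out = np.empty((len(self.frames), n_fib, 3))
        for t, f in enumerate(self.frames):
            for k in range(n_fib):
                sel = self.fiber_id == k
                out[t, k] = np.average(f.positions[sel], axis=0, weights=masses[sel])
        return out

    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])


class _Bodies:
    """Rigid-body bookkeeping for a System (composite groups + free beads)."""

    def __init__(self, system: System, ff: ForceField):
        n = system.n_beads
        masses = ff.masses(system.bead_class).astype(float)
        body_of = np.full(n, -1, dtype=int)
        groups = []
        for g in np.unique(system.rigid_group):
            if g < 0:
                continue
            groups.append(np.flatnonzero(system.rigid_group == g))
        free = np.flatnonzero(system.rigid_group < 0)
        members = groups + [np.array([i]) for i in free]
        for b, mem in enumerate(members):
            body_of[mem] = b
        self.members = members
        self.body_of = body_of
        self.n_bodies = len(members)
        self.mass = np.array([masses[m].sum() for m in members])
        self.bead_mass = masses

        # body-frame coordinates at initialization (body quat starts at identity)
        self.com = np.array([np.average(system.positions[m], axis=0, weights=masses[m]) for m in members])
        self.local_pos = system.positions - self.com[body_of]
        self.local_quat = system.quats.copy()
        self.quat = np.tile([1.0, 0.0, 0.0, 0.0], (self.n_bodies, 1))

        # isotropic inertia: mean principal moment + small per-bead sphere term
        bead_r2 = np.where(system.bead_class == model.HISTONE_CORE, 0.4 * 25.0**2, 0.4 * 10.0**2)
        r2 = np.sum(self.local_pos**2, axis=1)
        self.inertia = np.zeros(self.n_bodies)
        np.add.at(self.inertia, body_of, masses * ((2.0 / 3.0) * r2 + bead_r2))

    def bead_states(self):
        """Current per-bead positions and quats from body states (vectorized)."""
        q = self.quat[self.body_of]
        pos = self.com[self.body_of] + model._qrotate(q, self.local_pos)
        quat = model._qmul(q, self.local_quat)
        return pos, quat

    def gather(self, forces: np.ndarray, torques: np.ndarray, positions: np.ndarray):
        """Aggregate bead forces/torques to body forces and torques."""
        F = np.zeros((self.n_bodies, 3))
        T = np.zeros((self.n_bodies, 3))
        np.add.at(F, self.body_of, forces)
        np.add.at(T, self.body_of, torques + np.cross(positions - self.com[self.body_of], forces))
        return F, T


def _neighbor_pairs(positions, bead_class, pair_params, exclusions, box, skin: float = 0.0):
    """Exclusion-filtered candidate pairs within max cutoff (+ skin)."""
    rmax = max(p.r_cut for p in pair_params.values()) + skin
    pairs = model._candidate_pairs(positions, box, rmax)
    if len(pairs) and exclusions is not None and len(exclusions):
        lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        keys = lo * len(positions) + hi
        pairs = pairs[~np.isin(keys, exclusions)]
    return pairs


def _lj_forces(positions, bead_class, pair_params, exclusions, box, pairs=None):
    """Analytic LJ forces and energy over the candidate pair list."""
    if pairs is None:
        pairs = _neighbor_pairs(positions, bead_class, pair_params, exclusions, box)
    forces = np.zeros_like(positions)
    energy = 0.0
    if len(pairs) == 0:
        return forces, energy
    dr = model.minimum_image(positions[pairs[:, 1]] - positions[pairs[:, 0]], box)
    r = np.linalg.norm(dr, axis=1)
    keep = r < max(p.r_cut for p in pair_params.values())
    pairs, dr, r = pairs[keep], dr[keep], r[keep]
    if len(pairs) == 0:
        return forces, energy
    ci, cj = bead_class[pairs[:, 0]], bead_class[pairs[:, 1]]
    ncore = (ci == model.HISTONE_CORE).astype(int) + (cj == model.HISTONE_CORE).astype(int)
    fmag = np.zeros(len(pairs))
    for k, key in enumerate(("dna-dna", "dna-core", "core-core")):
        sel = ncore == k
        if np.any(sel):
            p = pair_params[key]
            fmag[sel] = model.pair_force_mag(r[sel], p)
            energy += float(np.sum(model.pair_energy(r[sel], p)))
    fvec = (fmag / r)[:, None] * dr  # force on j along +dr when repulsive
    np.add.at(forces, pairs[:, 1], fvec)
    np.add.at(forces, pairs[:, 0], -fvec)
    return forces, energy


_ROT_H = 1e-5  # rad, finite-difference step for orientational gradients


def _bonded_forces(positions, quats, bonded, rbp):
    """RBP bonded forces (analytic) and torques (finite difference)."""
    n = len(positions)
    forces = np.zeros((n, 3))
    torques = np.zeros((n, 3))
    if len(bonded) == 0:
        return forces, torques, 0.0
    i, j = bonded[:, 0], bonded[:, 1]

    phi, qmid = model._helical_step_full(positions[i], quats[i], positions[j], quats[j])
    energy = float(np.sum(model.rbp_energy(phi, rbp)))
    d = model._delta_phi(phi, rbp.phi0.as_array())
    grad = d @ rbp.K  # (m, 6) dE/dphi

    # analytic translational part: displacement = R_mid^T (r_j - r_i)
    f_trans = model._qrotate(qmid, grad[:, :3])
    np.add.at(forces, i, f_trans)
    np.add.at(forces, j, -f_trans)

    # orientational part: central differences of pair energies under small
    # world-frame rotations of either endpoint
    def pair_energies(qi, qj):
        ph = model._helical_step_arrays(positions[i], qi, positions[j], qj)
        return model.rbp_energy(ph, rbp)

    qi0, qj0 = quats[i], quats[j]
    for which, q0, other in ((0, qi0, qj0), (1, qj0, qi0)):
        tau = np.empty((len(bonded), 3))
        for a in range(3):
            axis = np.zeros(3)
            axis[a] = _ROT_H
            dq_p = model._rotvec_to_quat(axis)
            dq_m = model._rotvec_to_quat(-axis)
            qp = model._qmul(dq_p[None, :], q0)
            qm = model._qmul(dq_m[None, :], q0)
            if which == 0:
                ep = pair_energies(qp, other)
                em = pair_energies(qm, other)
            else:
                ep = pair_energies(other, qp)
                em = pair_energies(other, qm)
            tau[:, a] = -(ep - em) / (2.0 * _ROT_H)
        np.add.at(torques, i if which == 0 else j, tau)
    return forces, torques, energy


def compute_forces(
    positions, quats, system: System, ff: ForceField, salt: float, bias=None, masses=None, check: bool = True, pairs=None
):
    """Total forces/torques on beads and the potential energy.

    ``bias`` is an optional ``(cv, center, k)`` harmonic restraint on a
    collective variable with an analytic position gradient; ``pairs`` an
    optional cached neighbor list.
    """
    params = ff.pair_params(salt)
    f_lj, e_lj = _lj_forces(positions, system.bead_class, params, system.exclusions, system.box, pairs=pairs)
    f_b, t_b, e_b = _bonded_forces(positions, quats, system.bonded_pairs, ff.rbp)
    forces = f_lj + f_b
    energy = e_lj + e_b
    meta = {}
    if bias is not None:
        cv, center, k = bias
        tmp = system.copy()
        tmp.positions = positions
        val = cv.value(tmp, masses)
        grad = cv.gradient(tmp, masses)
        forces -= k * (val - center) * grad
        energy += 0.5 * k * (val - center) ** 2
        meta["cv"] = float(val)
        meta["bias_energy"] = float(0.5 * k * (val - center) ** 2)
    if check and (not np.all(np.isfinite(forces)) or np.max(np.abs(forces)) > _FORCE_LIMIT):
        bad = int(np.argmax(np.abs(forces).max(axis=1)))
        rr = np.linalg.norm(model.minimum_image(positions - positions[bad], system.box), axis=1)
        rr[bad] = np.inf
        other = int(np.argmin(rr))
        raise IntegrationError(f"force overflow on bead {bad} (closest partner {other}, r = {rr[other]:.3g} A)")
    return forces, t_b, energy, meta


def _scaled_forcefield(ff: ForceField, salt: float, scale: float) -> ForceField:
    """Force field with all pair sigmas scaled (soft-core minimization stages)."""
    from dataclasses import replace as dc_replace

    params = ff.pair_params(salt)
    scaled = {}
    for key, p in params.items():
        sigma = p.sigma * scale
        r_cut = sigma * 2 ** (1 / 6) if key == "dna-dna" else p.r_cut
        scaled[key] = dc_replace(p, sigma=sigma, r_cut=r_cut)
    out = ForceField(rbp=ff.rbp, pair_table={salt: scaled})
    out.mass_dna, out.mass_core = ff.mass_dna, ff.mass_core
    return out


def minimize_system(
    system: System,
    ff: ForceField,
    salt: float,
    max_steps: int = 500,
    max_disp: float = 0.5,
    max_rot: float = 0.02,
    ftol: float = 1.0,
    sigma_stages=(0.5, 0.75, 1.0),
):
    """Capped steepest-descent relaxation of a system's rigid bodies.

    Extended builds of short-linker fibers stack nucleosome discs into
    steric overlap (the zig-zag geometry), so relaxation runs in soft-core
    stages: pair sigmas are scaled up through ``sigma_stages`` so deeply
    interpenetrating bodies separate smoothly before the full excluded
    volume is applied.  Per step, body translations are capped at
    ``max_disp`` A and rotations at ``max_rot`` rad; each stage stops when
    the maximum bead force falls below ``ftol`` kcal/mol/A.  Modifies
    ``system`` in place and returns the final energy.
    """
    bodies = _Bodies(system, ff)
    positions, quats = bodies.bead_states()
    energy = np.inf
    for scale in sigma_stages:
        stage_ff = ff if scale == 1.0 else _scaled_forcefield(ff, salt, scale)
        for _ in range(max_steps):
            forces, torques, energy, _ = compute_forces(positions, quats, system, stage_ff, salt, check=False)
            fmax = np.max(np.abs(forces))
            if not np.isfinite(fmax):
                raise IntegrationError("non-finite forces during minimization")
            if fmax < ftol:
                break
            F, T = bodies.gather(forces, torques, positions)
            fnorm = np.linalg.norm(F, axis=1, keepdims=True)
            fbig = max(float(fnorm.max()), 1e-12)
            step = F * (np.minimum(max_disp, max_disp * fnorm / fbig) / np.maximum(fnorm, 1e-12))
            bodies.com += step
            tnorm = np.linalg.norm(T, axis=1, keepdims=True)
            tbig = max(float(tnorm.max()), 1e-12)
            ang = T * (np.minimum(max_rot, max_rot * tnorm / tbig) / np.maximum(tnorm, 1e-12))
            bodies.quat = (Rotation.from_rotvec(ang) * Rotation.from_quat(bodies.quat, scalar_first=True)).as_quat(
                scalar_first=True
            )
            positions, quats = bodies.bead_states()
    system.positions = positions
    system.quats = quats
    return float(energy)


class _Langevin:
    """BAOAB integrator state over the rigid bodies of one system."""

    def __init__(self, system: System, ff: ForceField, config: SimulationConfig, temperature: float, rng, bias=None):
        self.system = system
        self.ff = ff
        self.config = config
        self.T = float(temperature)
        self.rng = rng
        self.bias = bias
        self.bodies = _Bodies(system, ff)
        self.masses = ff.masses(system.bead_class)
        self.vel = np.zeros((self.bodies.n_bodies, 3))
        self.omega = np.zeros((self.bodies.n_bodies, 3))
        if self.T > 0:
            kT = KB * self.T * ACCEL
            self.vel = rng.standard_normal((self.bodies.n_bodies, 3)) * np.sqrt(kT / self.bodies.mass)[:, None]
            self.omega = rng.standard_normal((self.bodies.n_bodies, 3)) * np.sqrt(kT / self.bodies.inertia)[:, None]
        self.positions, self.quats = self.bodies.bead_states()
        self._nl_every = 20
        self._nl_skin = 10.0
        self._nl_pairs = None
        self._nl_age = 0
        self.forces, self.torques, self.energy, self.meta = self._forces()

    def _forces(self):
        if self._nl_pairs is None or self._nl_age >= self._nl_every:
            self._nl_pairs = _neighbor_pairs(
                self.positions,
                self.system.bead_class,
                self.ff.pair_params(self.config.salt),
                self.system.exclusions,
                self.system.box,
                skin=self._nl_skin,
            )
            self._nl_age = 0
        self._nl_age += 1
        f, t, e, meta = compute_forces(
            self.positions, self.quats, self.system, self.ff, self.config.salt, self.bias, self.masses, pairs=self._nl_pairs
        )
        return f, t, e, meta

    def _drift(self, dt):
        b = self.bodies
        b.com += self.vel * dt
        ang = self.omega * dt
        if np.any(ang):
            q = model._qmul(model._rotvec_to_quat(ang), b.quat)
            b.quat = q / np.linalg.norm(q, axis=-1, keepdims=True)

    def step(self, n: int = 1):
        dt = self.config.timestep
        gamma = self.config.friction
        kT = KB * self.T * ACCEL
        b = self.bodies
        c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        for _ in range(n):
            F, T = b.gather(self.forces, self.torques, self.positions)
            self.vel += 0.5 * dt * ACCEL * F / b.mass[:, None]
            self.omega += 0.5 * dt * ACCEL * T / b.inertia[:, None]
            self._drift(0.5 * dt)
            if gamma > 0:
                self.vel = c1 * self.vel + c2 * np.sqrt(kT / b.mass)[:, None] * self.rng.standard_normal(self.vel.shape)
                self.omega = (
                    c1 * self.omega
                    + c2 * np.sqrt(kT / b.inertia)[:, None] * self.rng.standard_normal(self.omega.shape)
                )
            if self.config.fix_com:
                vcom = np.average(self.vel, axis=0, weights=b.mass)
                self.vel -= vcom
            self._drift(0.5 * dt)
            self.positions, self.quats = b.bead_states()
            self.forces, self.torques, self.energy, self.meta = self._forces()
            F, T = b.gather(self.forces, self.torques, self.positions)
            self.vel += 0.5 * dt * ACCEL * F / b.mass[:, None]
            self.omega += 0.5 * dt * ACCEL * T / b.inertia[:, None]

    def kinetic_energy(self) -> float:
        ke = 0.5 * np.sum(self.bodies.mass[:, None] * self.vel**2)
        ke += 0.5 * np.sum(self.bodies.inertia[:, None] * self.omega**2)
        return float(ke / ACCEL)

    def scale_velocities(self, factor: float):
        self.vel *= factor
        self.omega *= factor


def run_langevin(state, ff: ForceField, config: SimulationConfig, bias=None) -> Trajectory:
    """Langevin dynamics of a System (or FiberState) under the force field.

    Identical seeds give identical trajectories.  Frames (positions, quats,
    potential energy, bias metadata) are recorded every ``output_stride``
    steps, including step 0.
    """
    system = System.from_fibers([state]) if isinstance(state, FiberState) else state
    if system.box is None and config.box is not None:
        system.box = np.asarray(config.box, dtype=float)
    temps = config.ladder()
    if len(temps) != 1:
        raise ValueError("run_langevin takes a single temperature; use run_remd for ladders")
    rng = np.random.default_rng(config.seed)
    integ = _Langevin(system, ff, config, temps[0], rng, bias=bias)
    traj = Trajectory(system, config.output_stride)
    traj.record(0, integ.positions, integ.quats, integ.energy, integ.meta)
    done = 0
    while done < config.n_steps:
        chunk = min(config.output_stride, config.n_steps - done)
        integ.step(chunk)
        done += chunk
        traj.record(done, integ.positions, integ.quats, integ.energy, integ.meta)
    return traj


def remd_accept(E_i, E_j, T_i, T_j, bias_i: float = 0.0, bias_j: float = 0.0) -> float:
    """Metropolis acceptance probability for swapping replicas i and j.

    The biasing potential is added to the total potential energy; the
    criterion is ``min(1, exp((beta_i - beta_j) * ((E_i + bias_i) -
    (E_j + bias_j))))`` and is symmetric under relabeling.
    """
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i, beta_j = 1.0 / (KB * T_i), 1.0 / (KB * T_j)
    delta = (beta_i - beta_j) * ((E_i + bias_i) - (E_j + bias_j))
    return float(min(1.0, np.exp(min(delta, 700.0))))


@dataclass
class REMDResult:
    cold_trajectory: Trajectory
    acceptance: dict
    temperatures: np.ndarray
    trajectories: list = None


def run_remd(state, ff: ForceField, config: SimulationConfig, bias=None, record_all: bool = False) -> REMDResult:
    """Temperature replica exchange over the configured ladder.

    Neighbor swaps are attempted every ``exchange_every`` steps with
    alternating pair parity; configurations are exchanged and velocities
    rescaled by ``sqrt(T_new/T_old)``.  Analysis uses the coldest replica,
    whose trajectory is recorded (all replicas with ``record_all``).
    """
    system = System.from_fibers([state]) if isinstance(state, FiberState) else state
    temps = config.ladder()
    if len(temps) < 2:
        raise ValueError("replica exchange needs at least two replicas")
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(len(temps) + 1)
    swap_rng = rngs[-1]
    reps = [
        _Langevin(system.copy(), ff, config, t, rngs[k], bias=bias) for k, t in enumerate(temps)
    ]
    cold = Trajectory(system, config.output_stride)
    all_traj = [Trajectory(system, config.output_stride) for _ in temps] if record_all else None
    attempts = np.zeros(len(temps) - 1)
    accepts = np.zeros(len(temps) - 1)

    n_rounds = max(1, config.n_steps // config.exchange_every)
    step = 0
    for rnd in range(n_rounds):
        for rep in reps:
            rep.step(config.exchange_every)
        step += config.exchange_every
        parity = rnd % 2
        for k in range(parity, len(temps) - 1, 2):
            a, b = reps[k], reps[k + 1]
            attempts[k] += 1
            ea = a.energy - a.meta.get("bias_energy", 0.0)
            eb = b.energy - b.meta.get("bias_energy", 0.0)
            p = remd_accept(ea, eb, temps[k], temps[k + 1], a.meta.get("bias_energy", 0.0), b.meta.get("bias_energy", 0.0))
            if swap_rng.random() < p:
                accepts[k] += 1
                _swap_configurations(a, b)
        if step % config.output_stride == 0 or config.output_stride <= config.exchange_every:
            cold.record(step, reps[0].positions, reps[0].quats, reps[0].energy, reps[0].meta)
            if record_all:
                for tr, rep in zip(all_traj, reps):
                    tr.record(step, rep.positions, rep.quats, rep.energy, rep.meta)
    acc = {
        "per_pair": (accepts / np.maximum(attempts, 1)).tolist(),
        "mean": float(accepts.sum() / max(1.0, attempts.sum())),
    }
    return REMDResult(cold_trajectory=cold, acceptance=acc, temperatures=temps, trajectories=all_traj)


def _swap_configurations(a: "_Langevin", b: "_Langevin"):
    for attr in ("com", "quat"):
        tmp = getattr(a.bodies, attr).copy()
        getattr(a.bodies, attr)[:] = getattr(b.bodies, attr)
        getattr(b.bodies, attr)[:] = tmp
    scale = np.sqrt(a.T / b.T)
    va, wa = a.vel.copy(), a.omega.copy()
    a.vel, a.omega = b.vel * scale, b.omega * scale
    b.vel, b.omega = va / scale, wa / scale
    for rep in (a, b):
        rep.positions, rep.quats = rep.bodies.bead_states()
        rep.forces, rep.torques, rep.energy, rep.meta = rep._forces()


def geometric_ladder(t_min: float = 300.0, t_max: float = 600.0, n: int = 8) -> np.ndarray:
    """Geometrically spaced temperature ladder."""
    if n < 2:
        raise ValueError("need at least two rungs")
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


def autosize_ladder(
    state, ff: ForceField, config: SimulationConfig, t_min=300.0, t_max=600.0, target: float = 0.3, tol: float = 0.1, n_max: int = 24
):
    """Pick a replica count whose mean swap acceptance is near the target.

    Runs short calibration REMD runs with geometric ladders of increasing
    size until the measured mean acceptance reaches ``target - tol``.
    """
    n = 2
    while n <= n_max:
        cfg = replace(config, temperatures=tuple(geometric_ladder(t_min, t_max, n)))
        result = run_remd(state, ff, cfg)
        if result.acceptance["mean"] >= target - tol:
            return cfg.ladder(), result.acceptance
        n += 2
    raise RuntimeError(f"could not reach target acceptance with <= {n_max} replicas")


def direct_coexistence_setup(
    n_fibers: int,
    topology: FiberTopology,
    box=(1200.0, 1200.0, 5000.0),
    salt: float = 150.0,
    seed: int = 0,
    slab_fraction: float = 1.0 / 3.0,
    min_separation: float = 80.0,
    max_retries: int = 2000,
) -> System:
    """Pack fibers into a dense slab at the center of an elongated box.

    Fibers are placed with random orientations at random positions within
    the central ``slab_fraction`` of the long (z) axis, rejecting placements
    whose nucleosome cores come within ``min_separation`` of an existing
    fiber.  Raises after ``max_retries`` failed placements.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    from .fiber import open_conformation
    from .fixtures import transform_fiber

    base = open_conformation(topology)

    core0 = topology.core_indices
    fibers = []
    placed_cores = []
    z_half = 0.5 * slab_fraction * box[2]
    tries = 0
    while len(fibers) < n_fibers:
        if tries > max_retries:
            raise IntegrationError(f"slab packing failed after {max_retries} retries")
        tries += 1
        rot = Rotation.random(rng=rng)
        center = np.array(
            [
                rng.uniform(0, box[0]),
                rng.uniform(0, box[1]),
                box[2] / 2.0 + rng.uniform(-z_half, z_half),
            ]
        )
        cand = transform_fiber(base, rotation=rot)
        shift = center - cand.positions[core0].mean(axis=0)
        cand = transform_fiber(cand, translation=shift)
        cores = cand.positions[core0]
        ok = True
        for prev in placed_cores:
            d = model.minimum_image(cores[:, None, :] - prev[None, :, :], box)
            if np.min(np.linalg.norm(d, axis=2)) < min_separation:
                ok = False
                break
        if ok:
            fibers.append(cand)
            placed_cores.append(cores)
    return System.from_fibers(fibers, box=box)


def slab_mass_density(system: System, ff: ForceField, slab_fraction: float = 1.0 / 3.0) -> float:
    """Mass density (g/L) of the central slab region of a periodic system."""
    from .phase import GRAMS_PER_LITER

    box = system.box
    masses = ff.masses(system.bead_class)
    z = np.mod(system.positions[:, 2], box[2])
    z_lo = box[2] * (0.5 - slab_fraction / 2.0)
    z_hi = box[2] * (0.5 + slab_fraction / 2.0)
    inside = (z >= z_lo) & (z < z_hi)
    volume = box[0] * box[1] * (z_hi - z_lo)
    return float(masses[inside].sum() / volume * GRAMS_PER_LITER)
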