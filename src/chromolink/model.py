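"""Energy model of the minimal coarse-grained chromatin fiber.

The model represents five DNA base pairs as one spherical rigid bead and the
histone core of each nucleosome as a single bead.  Two energy terms act:

* a rigid-base-pair (RBP) harmonic potential over the six helical step
  parameters ``(shift, slide, rise, tilt, roll, twist)`` of consecutive
  DNA beads, ``E = 1/2 (phi - phi0)^T K (phi - phi0)``, applied to linker
  steps and linker/nucleosome junctions (nucleosomal DNA is rigid);
* shifted-truncated Lennard-Jones pair potentials between beads, repulsive
  for DNA-DNA (screened electrostatic repulsion) and attractive for
  DNA-core and core-core (mean-field electrostatic attraction to the
  histone surface), with strengths that depend on monovalent salt.

Units are fixed repo-wide: Angstrom, kcal/mol, degrees, femtoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import check_unit, quat_to_matrix, wrap_angle

__all__ = [
    "KB",
    "BeadClass",
    "BeadState",
    "HelicalStep",
    "RBPParams",
    "LJPairParams",
    "ForceField",
    "helical_step",
    "helical_steps",
    "rbp_energy",
    "pair_energy",
    "system_energy",
]

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872

# integer bead-class codes used in array form
LINKER_DNA = 0
NUCLEOSOMAL_DNA = 1
HISTONE_CORE = 2

_CLASS_NAMES = {LINKER_DNA: "linker_DNA", NUCLEOSOMAL_DNA: "nucleosomal_DNA", HISTONE_CORE: "histone_core"}
_CLASS_CODES = {v: k for k, v in _CLASS_NAMES.items()}


class BeadClass:
    """Namespace of the three bead classes."""

    LINKER_DNA = LINKER_DNA
    NUCLEOSOMAL_DNA = NUCLEOSOMAL_DNA
    HISTONE_CORE = HISTONE_CORE

    names = _CLASS_NAMES
    codes = _CLASS_CODES

    @staticmethod
    def is_dna(code: int | np.ndarray):
        return np.asarray(code) != HISTONE_CORE


@dataclass(frozen=True)
class BeadState:
    """A single rigid bead: position (A), unit quaternion (scalar-first), class.

    The quaternion is validated to unit norm at construction; the class is
    immutable (the dataclass is frozen).
    """

    position: np.ndarray
    orientation: np.ndarray
    bead_class: str = "linker_DNA"

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        q = np.asarray(self.orientation, dtype=float)
        check_unit(q)
        object.__setattr__(self, "orientation", q)
        if self.bead_class not in _CLASS_CODES:
            raise ValueError(f"unknown bead class {self.bead_class!r}")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.orientation)


@dataclass
class HelicalStep:
    """Six helical step parameters: translations in A, rotations in degrees."""

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 0.0
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 0.0

    def as_array(self) -> np.ndarray:
        a = np.array([self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist], dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite helical step")
        return a

    @classmethod
    def from_array(cls, a) -> "HelicalStep":
        a = np.asarray(a, dtype=float)
        return cls(*a)


#: defaults parameterized against base-pair-resolution DNA simulations,
#: expressed per 5-bp bead step (rise 16.45 A ~ 3.29 A/bp; twist 172 deg
#: ~ 34.4 deg/bp).
DEFAULT_PHI0 = np.array([0.0, 0.0, 16.45, 0.0, 0.0, 172.0])
DEFAULT_KDIAG = np.array([0.301, 0.235, 1.56, 0.00614, 0.00515, 0.00724])


@dataclass
class RBPParams:
    """Equilibrium helical step and 6x6 stiffness of the bonded DNA potential.

    ``K`` is in kcal/mol per (A or degree)^2 and must be symmetric positive
    semidefinite; the default parameterization is diagonal.
    """

    phi0: HelicalStep = field(default_factory=lambda: HelicalStep.from_array(DEFAULT_PHI0))
    K: np.ndarray = field(default_factory=lambda: np.diag(DEFAULT_KDIAG))

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (6, 6):
            raise ValueError("K must be 6x6")
        if not np.allclose(self.K, self.K.T, atol=1e-12):
            raise ValueError("K must be symmetric")
        w = np.linalg.eigvalsh(self.K)
        if np.min(w) < -1e-10:
            raise ValueError("K must be positive semidefinite")


@dataclass
class LJPairParams:
    """Shifted-truncated Lennard-Jones parameters for one class pair.

    ``epsilon`` is the well depth (kcal/mol); the sign convention of the
    interaction (repulsive vs attractive) is carried by the cutoff: a purely
    repulsive pair truncates at the potential minimum (WCA style), an
    attractive pair truncates well beyond it.
    """

    epsilon: float
    sigma: float
    r_cut: float
    classes: tuple[str, str] = ("linker_DNA", "linker_DNA")

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma")


def _lj(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def pair_energy(r, params: LJPairParams):
    """Shifted-truncated LJ energy at separation ``r`` (A).

    ``E(r) = E_LJ(r) - E_LJ(r_cut)`` for ``r < r_cut`` and exactly zero
    beyond, so the potential is continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    shift = _lj(params.r_cut, params.epsilon, params.sigma)
    e = np.where(r < params.r_cut, _lj(np.minimum(r, params.r_cut), params.epsilon, params.sigma) - shift, 0.0)
    if e.ndim == 0:
        return float(e)
    return e


def pair_force_mag(r, params: LJPairParams):
    """Magnitude of -dE/dr (kcal/mol/A); positive = repulsive push."""
    r = np.asarray(r, dtype=float)
    sr6 = (params.sigma / r) ** 6
    f = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r < params.r_cut, f, 0.0)


def helical_step(frame_i: BeadState, frame_j: BeadState) -> HelicalStep:
    """Helical step parameters of the step i -> j in the mid-step frame.

    The relative rotation is split symmetrically between the two frames:
    translations are the displacement expressed in the mid-step frame,
    rotations are the components of the rotation vector of ``R_i^T R_j``
    (tilt about x, roll about y, twist about z), in degrees.
    """
    check_unit(frame_i.orientation)
    check_unit(frame_j.orientation)
    phi = _helical_step_arrays(
        frame_i.position[None], frame_i.orientation[None], frame_j.position[None], frame_j.orientation[None]
    )[0]
    return HelicalStep.from_array(phi)


# --- fast numpy quaternion kernels (scalar-first), used in the force loop ---


def _qmul(a, b):
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def _qconj(q):
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def _qrotate(q, v):
    """Rotate vectors v from body to world frame by quaternion q."""
    u = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def _quat_to_rotvec(q):
    w = np.clip(q[..., 0], -1.0, 1.0)
    vec = q[..., 1:]
    norm = np.linalg.norm(vec, axis=-1)
    angle = 2.0 * np.arctan2(norm, w)
    # map to (-pi, pi]
    angle = np.where(angle > np.pi, angle - 2.0 * np.pi, angle)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(norm > 1e-12, angle / np.where(norm > 1e-12, norm, 1.0), 2.0 / np.where(w == 0, 1.0, w))
    scale = np.where(norm > 1e-12, scale, 2.0)  # small-angle: rv ~ 2*vec/w ~ 2*vec
    return vec * scale[..., None]


def _rotvec_to_quat(rv):
    angle = np.linalg.norm(rv, axis=-1)
    half = 0.5 * angle
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(angle > 1e-12, np.sin(half) / np.where(angle > 1e-12, angle, 1.0), 0.5)
    return np.concatenate([np.cos(half)[..., None], rv * s[..., None]], axis=-1)


def _helical_step_full(ri, qi, rj, qj):
    """Helical parameters (n, 6) and the mid-step quaternion (n, 4)."""
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    qi = np.asarray(qi, dtype=float)
    qj = np.asarray(qj, dtype=float)
    rel = _qmul(_qconj(qi), qj)
    rel = np.where(rel[..., :1] < 0, -rel, rel)  # shortest arc
    rv = _quat_to_rotvec(rel)  # radians, frame i == mid frame for the axis
    qmid = _qmul(qi, _rotvec_to_quat(0.5 * rv))
    disp = _qrotate(_qconj(qmid), rj - ri)
    return np.concatenate([disp, np.degrees(rv)], axis=-1), qmid


def _helical_step_arrays(ri, qi, rj, qj):
    """Vectorized helical parameters for stacks of frame pairs -> (n, 6)."""
    return _helical_step_full(ri, qi, rj, qj)[0]


def helical_steps(positions, quats, pairs):
    """Helical parameters for ``pairs`` (m, 2) of bead indices -> (m, 6)."""
    pairs = np.asarray(pairs, dtype=int)
    return _helical_step_arrays(
        positions[pairs[:, 0]], quats[pairs[:, 0]], positions[pairs[:, 1]], quats[pairs[:, 1]]
    )


def _delta_phi(phi: np.ndarray, phi0: np.ndarray) -> np.ndarray:
    d = np.atleast_2d(phi) - phi0
    d[:, 5] = wrap_angle(d[:, 5])  # twist is periodic
    return d


def rbp_energy(step: HelicalStep | np.ndarray, params: RBPParams):
    """Harmonic rigid-base-pair energy ``1/2 dphi^T K dphi`` (kcal/mol).

    The twist deviation is wrapped to (-180, 180] degrees before the
    quadratic form is evaluated.
    """
    phi = step.as_array() if isinstance(step, HelicalStep) else np.asarray(step, dtype=float)
    scalar = phi.ndim == 1
    d = _delta_phi(phi, params.phi0.as_array())
    e = 0.5 * np.einsum("ni,ij,nj->n", d, params.K, d)
    return float(e[0]) if scalar else e


@dataclass
class ForceField:
    """Bonded RBP parameters plus a salt-resolved Lennard-Jones pair table.

    ``pair_table`` maps monovalent salt (mM) to the three class-pair
    potentials (DNA-DNA, DNA-core, core-core).  Between tabulated salts the
    well depths are linearly interpolated (geometry, i.e. sigma and r_cut,
    is salt-independent); requests outside the tabulated range raise.
    """

    rbp: RBPParams = field(default_factory=RBPParams)
    pair_table: dict = field(default_factory=dict)  # salt mM -> {pair key: LJPairParams}
    mass_dna: float = 3250.0  # g/mol per 5-bp bead
    mass_core: float = 108000.0  # g/mol histone octamer
    provenance: dict = field(default_factory=dict)

    PAIR_KEYS = ("dna-dna", "dna-core", "core-core")

    def salts(self):
        return sorted(self.pair_table)

    def pair_params(self, salt: float) -> dict:
        """Interpolated LJ parameters at ``salt`` mM."""
        salts = self.salts()
        if not salts:
            raise ValueError("empty pair table")
        if salt < salts[0] - 1e-9 or salt > salts[-1] + 1e-9:
            raise ValueError(f"salt {salt} mM outside tabulated range {salts[0]}-{salts[-1]} mM")
        if salt in self.pair_table:
            return self.pair_table[salt]
        hi = next(s for s in salts if s >= salt)
        lo = max(s for s in salts if s <= salt)
        if lo == hi:
            return self.pair_table[lo]
        t = (salt - lo) / (hi - lo)
        out = {}
        for key in self.PAIR_KEYS:
            a, b = self.pair_table[lo][key], self.pair_table[hi][key]
            out[key] = LJPairParams(
                epsilon=(1 - t) * a.epsilon + t * b.epsilon, sigma=a.sigma, r_cut=a.r_cut, classes=a.classes
            )
        return out

    def masses(self, bead_class: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(bead_class) == HISTONE_CORE, self.mass_core, self.mass_dna)

    def max_cutoff(self, salt: float) -> float:
        return max(p.r_cut for p in self.pair_params(salt).values())


def pair_key_for(class_i, class_j):
    """Map bead-class codes to the force-field pair key."""
    n_core = int(class_i == HISTONE_CORE) + int(class_j == HISTONE_CORE)
    return ("dna-dna", "dna-core", "core-core")[n_core]


def _candidate_pairs(positions, box, rmax):
    """All bead pairs within rmax (periodic if box is given) -> (m, 2) int."""
    n = len(positions)
    if box is not None:
        pos = np.mod(positions, box)
        tree = cKDTree(pos, boxsize=box)
    else:
        tree = cKDTree(positions)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    return pairs


def minimum_image(dr, box):
    if box is None:
        return dr
    return dr - np.round(dr / box) * box


def pair_energy_terms(positions, bead_class, pair_params, exclusions, box=None):
    """Total nonbonded energy and per-pair-key breakdown.

    ``exclusions`` lists bead-index pairs (bonded neighbors and
    same-rigid-group pairs) that do not interact, either as a collection of
    frozensets or, faster, as a sorted int64 array of keys ``i * N + j``
    with ``i < j`` (the encoding used by :class:`chromolink.fiber.System`).
    """
    rmax = max(p.r_cut for p in pair_params.values())
    pairs = _candidate_pairs(positions, box, rmax)
    out = {k: 0.0 for k in ("dna-dna", "dna-core", "core-core")}
    if len(pairs) == 0:
        return 0.0, out
    if exclusions is not None and len(exclusions):
        lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        if isinstance(exclusions, np.ndarray):
            keys = lo * len(positions) + hi
            mask = ~np.isin(keys, exclusions, assume_unique=False)
        else:
            excl = set(exclusions)
            mask = np.fromiter(
                (frozenset((int(a), int(b))) not in excl for a, b in zip(lo, hi)), dtype=bool, count=len(pairs)
            )
        pairs = pairs[mask]
    if len(pairs) == 0:
        return 0.0, out
    dr = minimum_image(positions[pairs[:, 1]] - positions[pairs[:, 0]], box)
    r = np.linalg.norm(dr, axis=1)
    ci, cj = bead_class[pairs[:, 0]], bead_class[pairs[:, 1]]
    ncore = (ci == HISTONE_CORE).astype(int) + (cj == HISTONE_CORE).astype(int)
    for k, key in enumerate(("dna-dna", "dna-core", "core-core")):
        sel = ncore == k
        if np.any(sel):
            out[key] = float(np.sum(pair_energy(r[sel], pair_params[key])))
    return sum(out.values()), out


def system_energy(system, ff: ForceField, salt: float) -> dict:
    """Total energy and per-term breakdown of a bead system.

    ``system`` provides ``positions`` (N, 3), ``quats`` (N, 4), ``bead_class``
    (N,), ``bonded_pairs`` (m, 2), ``exclusions`` and optionally ``box``.
    Returns a dict with keys ``bonded``, ``dna-dna``, ``dna-core``,
    ``core-core`` and ``total``; the breakdown sums to the total.
    """
    pos = np.asarray(system.positions, dtype=float)
    quats = np.asarray(system.quats, dtype=float)
    bonded = np.asarray(system.bonded_pairs, dtype=int)
    e_bond = 0.0
    if len(bonded):
        phi = helical_steps(pos, quats, bonded)
        e_bond = float(np.sum(rbp_energy(phi, ff.rbp)))
    params = ff.pair_params(salt)
    box = getattr(system, "box", None)
    e_pair, breakdown = pair_energy_terms(pos, np.asarray(system.bead_class), params, system.exclusions, box=box)
    out = {"bonded": e_bond, **breakdown}
    out["total"] = e_bond + e_pair
    return out
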