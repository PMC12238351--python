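"""Fiber topology construction and initial structures.

A chromatin array is specified by the number of nucleosomes, the base-pair
length of every linker, and the lengths of bare DNA flanking the terminal
nucleosomes.  The DNA is coarse-grained at five base pairs per bead by
tiling the whole fiber from its entry end; any trailing remainder of fewer
than five base pairs is discarded.  A bead takes the class (linker,
nucleosomal) of its central base pair, and all nucleosomal-DNA beads of a
nucleosome share a rigid group with its histone-core bead.

Nucleosome geometry is the canonical wrap: ~147 bp on a left-handed
superhelix of 1.65 turns, radius 41.8 A, pitch 25.4 A, so a nucleosome is a
disc roughly 110 A across and 55-60 A high.  Linker beads step along an
ideal helical axis at the equilibrium rise and twist (16.45 A, 172 deg per
bead, i.e. ~34.4 deg per bp), which makes the relative orientation of
successive nucleosomes a direct function of linker length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import model

__all__ = [
    "FiberTopology",
    "FiberState",
    "System",
    "build_fiber",
    "heterogeneous_linkers",
    "initialize_conformation",
    "open_conformation",
    "nucleosome_template",
]

BP_PER_BEAD = 5
NUCLEOSOMAL_BP_DEFAULT = 147

# canonical nucleosome wrap geometry
WRAP_TURNS = 1.65
WRAP_RADIUS = 41.8  # A
WRAP_PITCH = 25.4  # A per turn
TWIST_PER_BP = 172.0 / BP_PER_BEAD  # deg, equilibrium helical twist


@dataclass
class FiberTopology:
    """Bead-level description of one chromatin array."""

    n_nucleosomes: int
    linkers_bp: list[int]
    flank_bp: tuple[int, int]
    nucleosomal_bp: int = NUCLEOSOMAL_BP_DEFAULT
    # per-bead arrays, DNA beads first (chain order), core beads appended
    bead_class: np.ndarray = field(default=None, repr=False)
    rigid_group: np.ndarray = field(default=None, repr=False)
    nucleosome_of_bead: np.ndarray = field(default=None, repr=False)
    center_bp: np.ndarray = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        return (
            self.n_nucleosomes * self.nucleosomal_bp
            + int(sum(self.linkers_bp))
            + int(self.flank_bp[0])
            + int(self.flank_bp[1])
        )

    @property
    def n_dna_beads(self) -> int:
        return self.total_bp // BP_PER_BEAD

    @property
    def n_beads(self) -> int:
        return self.n_dna_beads + self.n_nucleosomes

    @property
    def core_indices(self) -> np.ndarray:
        return np.arange(self.n_dna_beads, self.n_beads)

    def bonded_pairs(self) -> np.ndarray:
        """Consecutive DNA bead steps that carry bonded energy.

        Steps internal to one rigid nucleosome group are excluded; linker
        steps and linker/nucleosome junctions remain.
        """
        i = np.arange(self.n_dna_beads - 1)
        g = self.rigid_group[: self.n_dna_beads]
        keep = ~((g[i] >= 0) & (g[i] == g[i + 1]))
        return np.stack([i[keep], i[keep] + 1], axis=1)

    def to_dict(self) -> dict:
        return {
            "schema": "chromolink-topology-1",
            "n_nucleosomes": int(self.n_nucleosomes),
            "linkers_bp": [int(x) for x in self.linkers_bp],
            "flank_bp": [int(self.flank_bp[0]), int(self.flank_bp[1])],
            "nucleosomal_bp": int(self.nucleosomal_bp),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberTopology":
        if d.get("schema") != "chromolink-topology-1":
            raise ValueError("unknown topology schema")
        topo = build_fiber(
            d["n_nucleosomes"],
            list(d["linkers_bp"]),
            tuple(d["flank_bp"]),
            nucleosomal_bp=d.get("nucleosomal_bp", NUCLEOSOMAL_BP_DEFAULT),
        )
        topo.metadata.update(d.get("metadata", {}))
        return topo


def build_fiber(n_nuc: int, linkers_bp, flank_bp=(0, 0), nucleosomal_bp=NUCLEOSOMAL_BP_DEFAULT) -> FiberTopology:
    """Construct a fiber topology for any linker-length pattern.

    ``linkers_bp`` may be a single integer (uniform linkers) or a list of
    length ``n_nuc - 1``.
    """
    if n_nuc < 1:
        raise ValueError("need at least one nucleosome")
    if np.isscalar(linkers_bp):
        linkers = [int(linkers_bp)] * (n_nuc - 1)
    else:
        linkers = [int(x) for x in linkers_bp]
        if len(linkers) != n_nuc - 1:
            raise ValueError(f"expected {n_nuc - 1} linkers, got {len(linkers)}")
    flank = (int(flank_bp[0]), int(flank_bp[1]))
    if any(x < 0 for x in linkers) or flank[0] < 0 or flank[1] < 0 or nucleosomal_bp < 0:
        raise ValueError("base-pair counts must be non-negative")

    topo = FiberTopology(n_nuc, linkers, flank, nucleosomal_bp)

    # per-bp class and nucleosome id along the chain
    segs = []  # (length, class, nuc_id)
    segs.append((flank[0], model.LINKER_DNA, -1))
    for k in range(n_nuc):
        segs.append((nucleosomal_bp, model.NUCLEOSOMAL_DNA, k))
        if k < n_nuc - 1:
            segs.append((linkers[k], model.LINKER_DNA, -1))
    segs.append((flank[1], model.LINKER_DNA, -1))
    bp_class = np.concatenate([np.full(n, c, dtype=int) for n, c, _ in segs if n > 0])
    bp_nuc = np.concatenate([np.full(n, g, dtype=int) for n, _, g in segs if n > 0])

    n_dna = topo.total_bp // BP_PER_BEAD
    center = BP_PER_BEAD * np.arange(n_dna) + BP_PER_BEAD // 2
    bead_class = bp_class[center]
    nuc_of_bead = bp_nuc[center]
    rigid = np.where(bead_class == model.NUCLEOSOMAL_DNA, nuc_of_bead, -1)

    # append core beads
    bead_class = np.concatenate([bead_class, np.full(n_nuc, model.HISTONE_CORE, dtype=int)])
    rigid = np.concatenate([rigid, np.arange(n_nuc)])
    nuc_of_bead = np.concatenate([nuc_of_bead, np.arange(n_nuc)])
    center = np.concatenate([center, np.full(n_nuc, -1, dtype=int)])

    topo.bead_class = bead_class
    topo.rigid_group = rigid
    topo.nucleosome_of_bead = nuc_of_bead
    topo.center_bp = center
    topo.metadata = {
        "wrap_turns": WRAP_TURNS,
        "wrap_radius": WRAP_RADIUS,
        "wrap_pitch": WRAP_PITCH,
        "twist_per_bp": TWIST_PER_BP,
        "discarded_bp": topo.total_bp % BP_PER_BEAD,
    }
    return topo


def heterogeneous_linkers(L: int, delta: int, n_nuc: int = 12) -> list[int]:
    """Linker list patterned ``[L+delta, L-delta, L]`` cycled over n_nuc-1 linkers.

    For a 12-nucleosome array this is the repeating heterogeneous pattern
    whose mean is exactly ``L``.
    """
    if L - delta < 0:
        raise ValueError("L - delta must be non-negative")
    base = [L + delta, L - delta, L]
    return [base[i % 3] for i in range(n_nuc - 1)]


def nucleosome_template(nucleosomal_bp: int = NUCLEOSOMAL_BP_DEFAULT):
    """Per-bp frames of the idealized wrap, in the nucleosome's own frame.

    Returns ``(positions(bp, 3), rotations Rotation(bp), core_position,
    core_rotation)``.  The disc normal (face axis) is the local +z; the wrap
    is left-handed and vertically centered so the core sits at the centroid.
    """
    b = np.arange(nucleosomal_bp, dtype=float)
    omega = WRAP_TURNS * 360.0 / nucleosomal_bp  # deg per bp around the axis
    alpha = -np.radians(omega * b)  # left-handed
    height = WRAP_TURNS * WRAP_PITCH
    z = (b / (nucleosomal_bp - 1) - 0.5) * height
    pos = np.stack([WRAP_RADIUS * np.cos(alpha), WRAP_RADIUS * np.sin(alpha), z], axis=1)

    # tangent frame with per-bp helical twist about the tangent
    dalpha = -np.radians(omega)
    dz = height / (nucleosomal_bp - 1)
    t = np.stack(
        [-WRAP_RADIUS * np.sin(alpha) * dalpha, WRAP_RADIUS * np.cos(alpha) * dalpha, np.full_like(alpha, dz)],
        axis=1,
    )
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    e_r = np.stack([np.cos(alpha), np.sin(alpha), np.zeros_like(alpha)], axis=1)
    x0 = e_r - np.sum(e_r * t, axis=1, keepdims=True) * t
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    y0 = np.cross(t, x0)
    psi = np.radians(TWIST_PER_BP * b)
    x = np.cos(psi)[:, None] * x0 + np.sin(psi)[:, None] * y0
    y = np.cross(t, x)
    mats = np.stack([x, y, t], axis=2)  # columns are local axes
    rots = Rotation.from_matrix(mats)
    core_pos = pos.mean(axis=0)
    core_rot = Rotation.identity()
    return pos, rots, core_pos, core_rot


def _equilibrium_step_transform(phi0: np.ndarray):
    """(Rotation, displacement-in-mid-frame) of one equilibrium bead step."""
    rot = Rotation.from_rotvec(np.radians(phi0[3:6]))
    return rot, phi0[0:3]


def _advance(rot_prev: Rotation, pos_prev: np.ndarray, phi: np.ndarray):
    """Place the next frame so that the helical step from prev equals phi."""
    step_rot = Rotation.from_rotvec(np.radians(phi[3:6]))
    half = Rotation.from_rotvec(0.5 * step_rot.as_rotvec())
    mid = rot_prev * half
    pos = pos_prev + mid.apply(phi[0:3])
    rot = rot_prev * step_rot
    return rot, pos


@dataclass
class FiberState:
    """A topology plus per-bead positions and orientations."""

    topology: FiberTopology
    positions: np.ndarray  # (n_beads, 3) A
    quats: np.ndarray  # (n_beads, 4) scalar-first

    def copy(self) -> "FiberState":
        return FiberState(self.topology, self.positions.copy(), self.quats.copy())

    def nucleosome_frames(self):
        """Centers and face normals of all nucleosomes (from core beads)."""
        idx = self.topology.core_indices
        centers = self.positions[idx]
        normals = Rotation.from_quat(self.quats[idx], scalar_first=True).apply(np.array([0.0, 0.0, 1.0]))
        return centers, normals


def initialize_conformation(topology: FiberTopology, mode: str = "extended", seed: int = 0) -> FiberState:
    """Build an initial conformation.

    ``extended`` places every linker step exactly at the equilibrium helical
    parameters (zero bonded energy); ``relaxed`` additionally runs a short
    seeded Langevin equilibration at 300 K and returns the final snapshot.
    """
    if mode not in ("extended", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "extended":
        return _build_extended(topology)

    # relaxed: start from the best opened build, remove residual overlaps,
    # then a short seeded Langevin equilibration
    from .dynamics import SimulationConfig, minimize_system, run_langevin
    from .forcefield import default_force_field

    ff = default_force_field()
    state = open_conformation(topology, ff)
    system = System.from_fibers([state])
    minimize_system(system, ff, 150.0, max_steps=100)
    config = SimulationConfig(temperatures=300.0, n_steps=200, seed=seed, output_stride=200, salt=150.0)
    traj = run_langevin(system, ff, config)
    sys_state = traj.final_system()
    return FiberState(topology, sys_state.positions.copy(), sys_state.quats.copy())


def open_conformation(topology: FiberTopology, ff=None, salt: float = 150.0) -> FiberState:
    """Lowest-energy gently-opened build over a small linker-offset grid.

    Strict equilibrium-step builds of short-linker fibers stack nucleosome
    discs into steric overlap; adding a few degrees of tilt/roll/twist per
    linker step opens the fiber at negligible bonded cost.  The grid search
    is deterministic and picks the build with the lowest total energy.
    """
    from .forcefield import default_force_field
    from .model import system_energy

    ff = ff or default_force_field()
    best_state, best_e = None, np.inf
    for dtilt in (0.0, 6.0, 12.0):
        for droll in (0.0, 6.0, 12.0):
            for dtwist in (0.0, 9.0, 18.0):
                st = _build_extended(topology, linker_offset=(dtilt, droll, dtwist))
                e = system_energy(System.from_fibers([st]), ff, salt)["total"]
                if e < best_e:
                    best_state, best_e = st, e
    return best_state


def _build_extended(topo: FiberTopology, linker_offset=(0.0, 0.0, 0.0)) -> FiberState:
    """Deterministic build with linker steps at phi0 (+ optional offsets).

    ``linker_offset`` adds (tilt, roll, twist) degrees per linker bead step,
    opening the fiber into a gently curved, clash-free conformation used to
    seed relaxation; zeros give the strict equilibrium-step build.
    """
    n_dna = topo.n_dna_beads
    phi0 = model.DEFAULT_PHI0
    tmpl_pos, tmpl_rot, tmpl_core_pos, tmpl_core_rot = nucleosome_template(topo.nucleosomal_bp)

    # per-bp start of each nucleosome along the chain
    nuc_start = np.zeros(topo.n_nucleosomes, dtype=int)
    bp = topo.flank_bp[0]
    for k in range(topo.n_nucleosomes):
        nuc_start[k] = bp
        bp += topo.nucleosomal_bp
        if k < topo.n_nucleosomes - 1:
            bp += topo.linkers_bp[k]

    positions = np.zeros((topo.n_beads, 3))
    rots: list[Rotation] = [None] * topo.n_beads
    anchor: dict[int, Rotation] = {}
    anchor_pos: dict[int, np.ndarray] = {}

    rot_prev, pos_prev = Rotation.identity(), np.zeros(3)
    for i in range(n_dna):
        nuc = topo.nucleosome_of_bead[i]
        if topo.bead_class[i] == model.NUCLEOSOMAL_DNA:
            b_loc = topo.center_bp[i] - nuc_start[nuc]
            if nuc not in anchor:
                # junction step at equilibrium: anchor the template here
                if i == 0:
                    rot_i, pos_i = Rotation.identity(), np.zeros(3)
                else:
                    rot_i, pos_i = _advance(rot_prev, pos_prev, phi0)
                t_rot = rot_i * tmpl_rot[b_loc].inv()
                anchor[nuc] = t_rot
                anchor_pos[nuc] = pos_i - t_rot.apply(tmpl_pos[b_loc])
            rot_i = anchor[nuc] * tmpl_rot[b_loc]
            pos_i = anchor_pos[nuc] + anchor[nuc].apply(tmpl_pos[b_loc])
        else:
            if i == 0:
                rot_i, pos_i = Rotation.identity(), np.zeros(3)
            else:
                phi = phi0
                if any(linker_offset):
                    phi = phi0.copy()
                    phi[3:6] += np.asarray(linker_offset, dtype=float)
                rot_i, pos_i = _advance(rot_prev, pos_prev, phi)
        positions[i] = pos_i
        rots[i] = rot_i
        rot_prev, pos_prev = rot_i, pos_i

    for k in range(topo.n_nucleosomes):
        j = n_dna + k
        if k not in anchor:  # nucleosome with no bead assigned (degenerate tiny fibers)
            anchor[k] = Rotation.identity()
            anchor_pos[k] = np.zeros(3)
        positions[j] = anchor_pos[k] + anchor[k].apply(tmpl_core_pos)
        rots[j] = anchor[k] * tmpl_core_rot

    quats = np.stack([r.as_quat(scalar_first=True) for r in rots])
    return FiberState(topo, positions, quats)


class System:
    """A collection of fibers sharing one (optionally periodic) box.

    Flattens per-fiber bead arrays into system-wide arrays and precomputes
    the nonbonded exclusions (bonded neighbors and same-rigid-group pairs)
    as sorted integer keys ``i * n_beads + j`` with ``i < j``.
    """

    def __init__(self, positions, quats, bead_class, rigid_group, bonded_pairs, fiber_id, nucleosome_id, topologies, box=None):
        self.positions = np.asarray(positions, dtype=float)
        self.quats = np.asarray(quats, dtype=float)
        self.bead_class = np.asarray(bead_class, dtype=int)
        self.rigid_group = np.asarray(rigid_group, dtype=int)
        self.bonded_pairs = np.asarray(bonded_pairs, dtype=int).reshape(-1, 2)
        self.fiber_id = np.asarray(fiber_id, dtype=int)
        self.nucleosome_id = np.asarray(nucleosome_id, dtype=int)
        self.topologies = list(topologies)
        self.box = None if box is None else np.asarray(box, dtype=float)
        self.exclusions = self._exclusion_keys()

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def _exclusion_keys(self) -> np.ndarray:
        n = self.n_beads
        keys = set()
        for i, j in self.bonded_pairs:
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            keys.add(a * n + b)
        for g in np.unique(self.rigid_group):
            if g < 0:
                continue
            members = np.flatnonzero(self.rigid_group == g)
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    keys.add(int(members[ai]) * n + int(members[bi]))
        return np.array(sorted(keys), dtype=np.int64)

    @classmethod
    def from_fibers(cls, fibers: list[FiberState], box=None) -> "System":
        pos, quats, cls_, rigid, bonded, fid, nid = [], [], [], [], [], [], []
        offset = 0
        group_offset = 0
        for f, st in enumerate(fibers):
            topo = st.topology
            pos.append(st.positions)
            quats.append(st.quats)
            cls_.append(topo.bead_class)
            rg = topo.rigid_group.copy()
            rg[rg >= 0] += group_offset
            rigid.append(rg)
            bonded.append(topo.bonded_pairs() + offset)
            fid.append(np.full(topo.n_beads, f, dtype=int))
            nid.append(topo.nucleosome_of_bead)
            offset += topo.n_beads
            group_offset += topo.n_nucleosomes
        return cls(
            np.concatenate(pos),
            np.concatenate(quats),
            np.concatenate(cls_),
            np.concatenate(rigid),
            np.concatenate(bonded),
            np.concatenate(fid),
            np.concatenate(nid),
            [st.topology for st in fibers],
            box=box,
        )

    def fiber_states(self) -> list[FiberState]:
        out = []
        offset = 0
        for topo in self.topologies:
            n = topo.n_beads
            out.append(FiberState(topo, self.positions[offset : offset + n].copy(), self.quats[offset : offset + n].copy()))
            offset += n
        return out

    def copy(self) -> "System":
        new = System.__new__(System)
        new.positions = self.positions.copy()
        new.quats = self.quats.copy()
        for attr in ("bead_class", "rigid_group", "bonded_pairs", "fiber_id", "nucleosome_id", "exclusions"):
            setattr(new, attr, getattr(self, attr))
        new.topologies = self.topologies
        new.box = None if self.box is None else self.box.copy()
        return new
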