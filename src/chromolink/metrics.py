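"""Structural analysis of nucleosome arrays and condensates.

Contacts between nucleosomes are classified from core-bead centers and disc
normals into face-to-face, face-to-side and side-to-side types using a
single distance cutoff (120 A) and a single angular threshold (45 deg).
The three printed definitions overlap, so classification is an exclusive
decision tree with precedence face_face -> face_side -> side_side; all
axis angles are folded to [0, 90] deg because a nucleosome disc is
two-sided.

Also here: the zig-zag (i, i+2 stacking) fraction, inter-fiber valence,
reference-free dRMSD, seeded k-medoids clustering in dRMSD space, and
diffusion coefficients from mean squared displacements with block-averaged
uncertainties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "NucleosomeFrame",
    "ContactRecord",
    "DiffusionResult",
    "classify_contact",
    "classify_contacts",
    "contact_records",
    "zigzag_fraction",
    "interfiber_valence",
    "drmsd",
    "kmeans_structures",
    "msd_curve",
    "msd_diffusion",
    "autocorrelation_time",
]

CONTACT_CUTOFF = 120.0  # A
CONTACT_ANGLE = 45.0  # deg

CONTACT_TYPES = ("face_face", "face_side", "side_side")


@dataclass(frozen=True)
class NucleosomeFrame:
    """Center and face normal of one nucleosome."""

    center: np.ndarray
    normal: np.ndarray
    fiber: int = 0
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("face normal must be unit length")
        object.__setattr__(self, "normal", n / norm)


@dataclass(frozen=True)
class ContactRecord:
    pair: tuple[tuple[int, int], tuple[int, int]]  # ((fiber, index), (fiber, index))
    type: str
    distance: float


def _fold(angle_deg: np.ndarray) -> np.ndarray:
    """Fold an angle between undirected axes into [0, 90] degrees."""
    a = np.asarray(angle_deg, dtype=float) % 180.0
    return np.minimum(a, 180.0 - a)


def _axis_angle(u, v) -> np.ndarray:
    cosang = np.clip(np.abs(np.sum(u * v, axis=-1)), 0.0, 1.0)
    return np.degrees(np.arccos(cosang))


def classify_contacts(centers_a, normals_a, centers_b, normals_b, cutoff=CONTACT_CUTOFF, angle=CONTACT_ANGLE):
    """Vectorized contact classification for paired frame arrays.

    Returns an int array: -1 no contact, else index into CONTACT_TYPES.
    """
    ca = np.atleast_2d(centers_a)
    cb = np.atleast_2d(centers_b)
    na = np.atleast_2d(normals_a)
    nb = np.atleast_2d(normals_b)
    d = cb - ca
    r = np.linalg.norm(d, axis=-1)
    if np.any(r == 0):
        raise ValueError("degenerate geometry: coincident nucleosome centers")
    u = d / r[..., None]
    axis_axis = _axis_angle(na, nb)
    a_to_c = _axis_angle(na, u)
    b_to_c = _axis_angle(nb, u)
    out = np.full(r.shape, -1, dtype=int)
    within = r < cutoff
    ff = within & (axis_axis < angle)
    aligned_a = a_to_c < angle
    aligned_b = b_to_c < angle
    fs = within & ~ff & (aligned_a ^ aligned_b)
    ss = within & ~ff & ~fs
    out[ff] = 0
    out[fs] = 1
    out[ss] = 2
    return out


def classify_contact(a: NucleosomeFrame, b: NucleosomeFrame, cutoff=CONTACT_CUTOFF, angle=CONTACT_ANGLE):
    """Classify one nucleosome pair; returns a ContactRecord or None.

    Symmetric in its arguments by construction (all tests are on undirected
    axes or involve both frames the same way).
    """
    code = classify_contacts(a.center[None], a.normal[None], b.center[None], b.normal[None], cutoff, angle)[0]
    if code < 0:
        return None
    return ContactRecord(
        pair=((a.fiber, a.index), (b.fiber, b.index)),
        type=CONTACT_TYPES[code],
        distance=float(np.linalg.norm(a.center - b.center)),
    )


def system_nucleosome_frames(system):
    """Centers, normals, fiber ids and in-fiber indices of all core beads."""
    from scipy.spatial.transform import Rotation

    from .model import HISTONE_CORE

    sel = np.flatnonzero(system.bead_class == HISTONE_CORE)
    centers = system.positions[sel]
    normals = Rotation.from_quat(system.quats[sel], scalar_first=True).apply(np.array([0.0, 0.0, 1.0]))
    return centers, normals, system.fiber_id[sel], system.nucleosome_id[sel]


def contact_records(system, cutoff=CONTACT_CUTOFF, angle=CONTACT_ANGLE) -> list[ContactRecord]:
    """All classified nucleosome-nucleosome contacts in one snapshot."""
    centers, normals, fibers, indices = system_nucleosome_frames(system)
    n = len(centers)
    ii, jj = np.triu_indices(n, k=1)
    codes = classify_contacts(centers[ii], normals[ii], centers[jj], normals[jj], cutoff, angle)
    out = []
    for a, b, c in zip(ii, jj, codes):
        if c < 0:
            continue
        out.append(
            ContactRecord(
                pair=((int(fibers[a]), int(indices[a])), (int(fibers[b]), int(indices[b]))),
                type=CONTACT_TYPES[c],
                distance=float(np.linalg.norm(centers[a] - centers[b])),
            )
        )
    return out


def zigzag_fraction(frames, cutoff=CONTACT_CUTOFF, angle=CONTACT_ANGLE) -> dict:
    """Fraction of (i, i+2) intra-fiber contacts among second neighbors.

    ``frames`` is a sequence of snapshots, each either a System or a list of
    FiberStates.  Counts are normalized by the total number of nucleosomes
    in one fiber times the number of frames; fibers with fewer than three
    nucleosomes contribute zero by convention.  Returned per contact type
    plus ``total``.
    """
    counts = {t: 0.0 for t in CONTACT_TYPES}
    n_frames = 0
    n_nuc_per_fiber = None
    for snap in frames:
        fiber_list = snap.fiber_states() if hasattr(snap, "fiber_states") else list(snap)
        n_frames += 1
        for st in fiber_list:
            centers, normals = st.nucleosome_frames()
            n = len(centers)
            if n_nuc_per_fiber is None:
                n_nuc_per_fiber = n
            if n < 3:
                continue
            i = np.arange(n - 2)
            codes = classify_contacts(centers[i], normals[i], centers[i + 2], normals[i + 2], cutoff, angle)
            for k, t in enumerate(CONTACT_TYPES):
                counts[t] += float(np.sum(codes == k))
    if n_frames == 0 or not n_nuc_per_fiber:
        return {**{t: 0.0 for t in CONTACT_TYPES}, "total": 0.0}
    norm = n_nuc_per_fiber * n_frames
    out = {t: counts[t] / norm for t in CONTACT_TYPES}
    out["total"] = sum(counts.values()) / norm
    return out


def interfiber_valence(system, cutoff=CONTACT_CUTOFF, angle=CONTACT_ANGLE) -> dict:
    """Number of neighboring fibers each fiber contacts in one snapshot.

    Fiber j neighbors fiber i when any nucleosome pair across them is in
    contact (any type).  Returns the per-fiber counts plus box-plot
    statistics (median, quartiles, min/max, outliers by the 1.5 IQR rule).
    """
    records = contact_records(system, cutoff, angle)
    n_fibers = len(system.topologies)
    neighbors = {i: set() for i in range(n_fibers)}
    for rec in records:
        (fa, _), (fb, _) = rec.pair
        if fa != fb:
            neighbors[fa].add(fb)
            neighbors[fb].add(fa)
    counts = np.array([len(neighbors[i]) for i in range(n_fibers)], dtype=float)
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    iqr = q3 - q1
    outliers = counts[(counts < q1 - 1.5 * iqr) | (counts > q3 + 1.5 * iqr)]
    return {
        "counts": counts,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(np.min(counts)),
        "max": float(np.max(counts)),
        "outliers": outliers,
    }


def _centers_of(structure) -> np.ndarray:
    if hasattr(structure, "nucleosome_frames"):
        return structure.nucleosome_frames()[0]
    return np.asarray(structure, dtype=float)


def drmsd(A, B) -> float:
    """Distance-matrix RMSD between two nucleosome-center structures (A).

    ``sqrt( 2/(N(N-1)) * sum_{i<j} (d_ij(A) - d_ij(B))^2 )`` over the
    intramolecular center-center distances; invariant under rigid
    transformations of either structure, symmetric, and zero iff the two
    distance matrices coincide.
    """
    xa = _centers_of(A)
    xb = _centers_of(B)
    if xa.shape != xb.shape:
        raise ValueError(f"mismatched structure sizes {xa.shape} vs {xb.shape}")
    n = len(xa)
    if n < 2:
        raise ValueError("need at least two nucleosomes")
    da = pdist(xa)
    db = pdist(xb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def _drmsd_matrix(structures) -> np.ndarray:
    dists = [pdist(_centers_of(s)) for s in structures]
    n = len(dists)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = np.sqrt(np.mean((dists[i] - dists[j]) ** 2))
    return out


def kmeans_structures(structures, k: int = 20, max_iter: int = 1000, seed: int = 0):
    """K-means in dRMSD space with medoid centers (k-medoids).

    Because dRMSD is not a Euclidean embedding, cluster centers are medoids
    (the member minimizing the summed squared dRMSD to its cluster); both
    the assignment and the medoid update are non-increasing in the
    objective.  Initialization picks k distinct random structures with the
    given seed.  Returns ``(labels, medoid indices, objective history)``.
    """
    n = len(structures)
    if n < k:
        raise ValueError(f"need at least k={k} structures, got {n}")
    D = _drmsd_matrix(structures)
    # collapse exact duplicates for seeding
    distinct = []
    for i in range(n):
        if all(D[i, j] > 1e-12 for j in distinct):
            distinct.append(i)
    k_eff = min(k, len(distinct))
    if k_eff < k:
        warnings.warn(f"only {k_eff} distinct structures; reducing k from {k}", RuntimeWarning)
    rng = np.random.default_rng(seed)
    medoids = rng.choice(distinct, size=k_eff, replace=False)
    history = []
    labels = np.argmin(D[:, medoids] ** 2, axis=1)
    for _ in range(int(max_iter)):
        obj = float(np.sum(D[np.arange(n), medoids[labels]] ** 2))
        history.append(obj)
        new_medoids = medoids.copy()
        for c in range(k_eff):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)] ** 2
            new_medoids[c] = members[np.argmin(within.sum(axis=1))]
        new_labels = np.argmin(D[:, new_medoids] ** 2, axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids, np.array(history)


def autocorrelation_time(series, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time of a scalar series, in frames.

    Computed as ``1 + 2 * sum(rho_k)`` with the sum truncated at the first
    non-positive autocorrelation (initial positive sequence estimator).
    Returns 1.0 for white noise; used to gauge how often recorded frames
    are statistically independent.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 3:
        raise ValueError("need at least three samples")
    var = float(np.dot(x, x)) / n
    if var == 0:
        return 1.0
    if max_lag is None:
        max_lag = n // 2
    tau = 1.0
    for lag in range(1, max_lag):
        rho = float(np.dot(x[:-lag], x[lag:])) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return tau


@dataclass
class DiffusionResult:
    """Diffusion coefficient from the linear regime of the MSD."""

    D: float  # A^2 per timestep
    uncertainty: float
    lags: np.ndarray = field(repr=False, default=None)
    msd: np.ndarray = field(repr=False, default=None)

    def normalized(self, reference: "DiffusionResult") -> float:
        return self.D / reference.D


def msd_curve(com_traj: np.ndarray, max_lag: int | None = None):
    """Time-averaged MSD over lags for one or more tracked centers.

    ``com_traj`` has shape (n_frames, 3) or (n_frames, n_tracks, 3);
    averaging runs over both time origins and tracks.
    """
    x = np.asarray(com_traj, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two frames")
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for i, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        msd[i] = np.mean(np.sum(d * d, axis=-1))
    return lags, msd


def msd_diffusion(com_traj, fit_range=None, n_blocks: int = 5, frame_dt: float = 1.0) -> DiffusionResult:
    """Diffusion coefficient D = slope/6 with block-averaged uncertainty.

    ``fit_range`` is a (lo, hi) lag-index pair into the MSD curve (default
    the central half, excluding the shortest ballistic lags); the
    uncertainty is the standard error of D over ``n_blocks`` contiguous
    trajectory blocks.  ``frame_dt`` converts frame lags to timesteps.
    """
    x = np.asarray(com_traj, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    n = len(x)
    lags, msd = msd_curve(x)
    if fit_range is None:
        fit_range = (max(1, len(lags) // 4), len(lags))
    lo, hi = fit_range
    if hi > len(lags):
        raise ValueError(f"fit range {fit_range} exceeds max lag {len(lags)}")
    t = lags[lo:hi] * frame_dt
    slope = np.polyfit(t, msd[lo:hi], 1)[0]
    D = max(slope / 6.0, 0.0)

    block_ds = []
    block_len = n // n_blocks
    if block_len >= 4:
        for b in range(n_blocks):
            seg = x[b * block_len : (b + 1) * block_len]
            bl, bm = msd_curve(seg)
            blo = max(1, len(bl) // 4)
            tb = bl[blo:] * frame_dt
            if len(tb) >= 2:
                s = np.polyfit(tb, bm[blo:], 1)[0]
                block_ds.append(max(s / 6.0, 0.0))
    err = float(np.std(block_ds) / np.sqrt(len(block_ds))) if len(block_ds) > 1 else 0.0
    return DiffusionResult(D=float(D), uncertainty=err, lags=lags, msd=msd)
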