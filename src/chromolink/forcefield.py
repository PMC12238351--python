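"""Force-field construction, serialization, and pair-potential calibration.

The shipped force field combines the rigid-base-pair bonded parameters with
a table of Lennard-Jones pair potentials keyed by monovalent salt (mM).
DNA-DNA interactions are purely repulsive (WCA-truncated), standing in for
screened electrostatic repulsion between phosphate backbones; DNA-core and
core-core interactions are attractive, standing in for the mean-field
attraction between DNA and the positively charged histone surface.

Because the model has no explicit ions, salt enters only through a monotone
multiplier on the attractive well depths: higher monovalent salt screens
DNA-DNA repulsion more strongly, which at this resolution is equivalent to
deepening the net internucleosome attraction.  The 150 mM entry is the
calibration anchor: its well depths are tuned (see :func:`calibrate_pair_table`)
so that the face-to-face nucleosome-pair interaction minimum is ~-4.8
kcal/mol near 60 A and the side-to-side minimum ~-0.8 kcal/mol near 110 A,
with face-to-side intermediate near 75 A.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import numpy as np
import yaml

from .model import ForceField, HelicalStep, LJPairParams, RBPParams

__all__ = [
    "default_force_field",
    "load_force_field",
    "save_force_field",
    "build_force_field",
    "calibrate_pair_table",
]

#: multiplier applied to the attractive well depths at each tabulated salt,
#: relative to the 150 mM calibration point; monotone increasing (screening).
SALT_MULTIPLIERS = {50.0: 0.55, 100.0: 0.80, 150.0: 1.00, 200.0: 1.15, 250.0: 1.28}


def build_force_field(pair_150: dict, salt_multipliers: dict | None = None, provenance: dict | None = None) -> ForceField:
    """Assemble a :class:`ForceField` from 150 mM pair parameters.

    ``pair_150`` maps the three pair keys to ``(epsilon, sigma, r_cut)``
    tuples; attractive depths at other salts are scaled by the multiplier
    table while the repulsive DNA-DNA term is salt-independent.
    """
    mult = dict(SALT_MULTIPLIERS if salt_multipliers is None else salt_multipliers)
    table = {}
    for salt, m in sorted(mult.items()):
        entry = {}
        for key, (eps, sigma, r_cut) in pair_150.items():
            scale = 1.0 if key == "dna-dna" else m
            entry[key] = LJPairParams(epsilon=eps * scale, sigma=sigma, r_cut=r_cut, classes=_classes_for(key))
        table[float(salt)] = entry
    return ForceField(rbp=RBPParams(), pair_table=table, provenance=provenance or {})


def _classes_for(key: str) -> tuple[str, str]:
    return {
        "dna-dna": ("linker_DNA", "linker_DNA"),
        "dna-core": ("linker_DNA", "histone_core"),
        "core-core": ("histone_core", "histone_core"),
    }[key]


def save_force_field(ff: ForceField, path) -> None:
    doc = {
        "schema": "chromolink-forcefield-1",
        "units": {"length": "angstrom", "energy": "kcal/mol", "angle": "degree", "salt": "mM"},
        "rbp": {
            "phi0": [float(x) for x in ff.rbp.phi0.as_array()],
            "K_diag": [float(x) for x in np.diag(ff.rbp.K)],
        },
        "masses": {"dna_bead": ff.mass_dna, "core_bead": ff.mass_core},
        "pair_table": {
            float(salt): {
                key: {"epsilon": float(p.epsilon), "sigma": float(p.sigma), "r_cut": float(p.r_cut)}
                for key, p in entry.items()
            }
            for salt, entry in ff.pair_table.items()
        },
        "provenance": ff.provenance,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_force_field(path) -> ForceField:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema") != "chromolink-forcefield-1":
        raise ValueError("unknown force-field schema")
    rbp = RBPParams(phi0=HelicalStep.from_array(doc["rbp"]["phi0"]), K=np.diag(doc["rbp"]["K_diag"]))
    table = {}
    for salt, entry in doc["pair_table"].items():
        table[float(salt)] = {
            key: LJPairParams(epsilon=v["epsilon"], sigma=v["sigma"], r_cut=v["r_cut"], classes=_classes_for(key))
            for key, v in entry.items()
        }
    ff = ForceField(rbp=rbp, pair_table=table, provenance=doc.get("provenance", {}))
    ff.mass_dna = doc["masses"]["dna_bead"]
    ff.mass_core = doc["masses"]["core_bead"]
    return ff


def default_force_field() -> ForceField:
    """The force field shipped with the package (calibrated at 150 mM)."""
    ref = resources.files("chromolink.data").joinpath("forcefield.yaml")
    with resources.as_file(ref) as path:
        return load_force_field(path)


def pair_interaction_energy(state_a, state_b, ff: ForceField, salt: float) -> float:
    """Inter-fiber nonbonded energy between two fiber states (kcal/mol)."""
    from .model import pair_energy

    params = ff.pair_params(salt)
    ca = state_a.topology.bead_class
    cb = state_b.topology.bead_class
    total = 0.0
    for key, (ma, mb) in {
        "dna-dna": (ca != 2, cb != 2),
        "dna-core": (None, None),  # handled below, two orientations
        "core-core": (ca == 2, cb == 2),
    }.items():
        if key == "dna-core":
            continue
        d = np.linalg.norm(state_a.positions[ma][:, None, :] - state_b.positions[mb][None, :, :], axis=2)
        total += float(np.sum(pair_energy(d.ravel(), params[key])))
    for ma, mb in (((ca != 2), (cb == 2)), ((ca == 2), (cb != 2))):
        d = np.linalg.norm(state_a.positions[ma][:, None, :] - state_b.positions[mb][None, :, :], axis=2)
        total += float(np.sum(pair_energy(d.ravel(), params["dna-core"])))
    return total


def pair_geometry_profile(geometry: str, distances, ff: ForceField, salt: float = 150.0):
    """Inter-fiber energy of an idealized nucleosome pair versus separation.

    ``geometry`` is one of ``face_face``, ``face_side``, ``side_side``;
    returns ``(distances, energies)`` arrays.  Used for calibration and as
    the deterministic stand-in for the orientation-restrained pair scans.
    """
    from .fixtures import make_stacked_pair_fixture

    distances = np.asarray(distances, dtype=float)
    energies = np.empty_like(distances)
    for i, d in enumerate(distances):
        _, _, sa, sb = make_stacked_pair_fixture(geometry, d)
        energies[i] = pair_interaction_energy(sa, sb, ff, salt)
    return distances, energies


def calibrate_pair_table(
    targets=None,
    x0=None,
    maxiter: int = 400,
    w_dist: float = 3.0,
    w_depth: float = 0.25,
):
    """Tune the 150 mM pair parameters against the pair-geometry anchors.

    ``targets`` maps geometry name to ``(distance A, depth kcal/mol)``;
    defaults are the face-to-face (60, -4.8), face-to-side (75, -4.2) and
    side-to-side (110, -0.8) anchors.  Optimizes ``(sigma_dd, sigma_dc,
    eps_dc, sigma_cc, eps_cc)`` by Nelder-Mead on a weighted squared error
    of quadratic-interpolated minimum locations and depths; returns
    ``(pair_150 dict, diagnostics dict)``.
    """
    from scipy.optimize import minimize

    from .free_energy import profile_minimum

    if targets is None:
        targets = {"face_face": (60.0, -4.8), "face_side": (75.0, -4.2), "side_side": (110.0, -0.8)}
    grid = {g: np.arange(max(30.0, t[0] - 35.0), t[0] + 60.0, 1.0) for g, t in targets.items()}

    def make_table(p):
        s_dd, s_dc, e_dc, s_cc, e_cc = p
        return {
            "dna-dna": (0.5, s_dd, s_dd * 2 ** (1 / 6)),  # WCA: purely repulsive
            "dna-core": (e_dc, s_dc, 120.0),
            "core-core": (e_cc, s_cc, 140.0),
        }

    def objective(p):
        if np.any(np.asarray(p) <= 0):
            return 1e6
        ff = build_force_field(make_table(p))
        err = 0.0
        for g, (d_t, e_t) in targets.items():
            d, e = pair_geometry_profile(g, grid[g], ff, 150.0)
            loc, depth = profile_minimum(d, e)
            if loc is None:
                return 1e6
            err += ((loc - d_t) / w_dist) ** 2 + ((depth - e_t) / w_depth) ** 2
        return err

    if x0 is None:
        x0 = np.array([25.9, 29.7, 1.0, 54.7, 3.4])
    res = minimize(objective, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4})
    table = make_table(res.x)
    ff = build_force_field(table)
    diag = {"objective": float(res.fun), "x": [float(v) for v in res.x]}
    for g, (d_t, e_t) in targets.items():
        d, e = pair_geometry_profile(g, grid[g], ff, 150.0)
        loc, depth = profile_minimum(d, e)
        diag[g] = {"distance": loc, "depth": depth, "target": [d_t, e_t]}
    return table, diag
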