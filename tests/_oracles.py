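"""Independent oracles the tests compare the implementation against.

Each oracle recomputes a quantity by the most direct method available
(flood fill, exhaustive Cartesian construction, double loops, generic
constrained optimization) without sharing code paths with the module it
checks.
"""

import itertools

import numpy as np
from scipy.optimize import minimize

from confenum.geometry_core import (
    build_backbone,
    improper_ok,
    steric_ok,
)
from confenum.ibp_enumerator import ca_rmsd, torsion_samples
from confenum.torsion_priors import GRID_SIZE


def floodfill_components(voxels):
    """8-connected components with toroidal wrap, by explicit flood fill."""
    voxels = set(voxels)
    seen = set()
    comps = []
    for start in sorted(voxels):
        if start in seen:
            continue
        comp = set()
        queue = [start]
        while queue:
            cell = queue.pop()
            if cell in seen:
                continue
            seen.add(cell)
            comp.add(cell)
            a, b = cell
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    nb = ((a + da) % GRID_SIZE, (b + db) % GRID_SIZE)
                    if nb in voxels and nb not in seen:
                        queue.append(nb)
        comps.append(comp)
    return comps


def brute_force_enumerate(spec, assignment, settings, params):
    """Cartesian torsion-grid construction replicating the enumerator's
    branching, with whole-conformation pruning and gating.

    Builds every sampled torsion combination directly with the chain
    constructor (no trilateration), checks sterics/impropers on the full
    dummy-flanked chain, strips the dummies and applies the save gate in
    the same traversal order the depth-first enumerator uses.
    """
    inner = spec.inner_resids()
    flat = []
    for rid in inner:
        box = assignment[rid]
        flat.append(
            [
                t
                for sub in torsion_samples(box.phi_lo, box.phi_hi, "phi", settings, params)
                for t in sub
            ]
        )
        flat.append(
            [
                t
                for sub in torsion_samples(box.psi_lo, box.psi_hi, "psi", settings, params)
                for t in sub
            ]
        )
    saved = []
    seq_full = "A" + spec.sequence + "A"
    for combo in itertools.product(*flat):
        torsions = (
            [(0.0, 180.0)]
            + [(combo[2 * k], combo[2 * k + 1]) for k in range(len(inner))]
            + [(180.0, 0.0)]
        )
        full = build_backbone(
            seq_full, torsions, params, start_resid=spec.start_resid - 1
        )
        if not steric_ok(full, params, settings.vdw_scale):
            continue
        if not improper_ok(full, params, settings.improper_tol):
            continue
        conf = full.select_resids(inner)
        if (
            settings.save_rmsd_gate > 0
            and saved
            and ca_rmsd(conf, saved[-1]) <= settings.save_rmsd_gate
        ):
            continue
        saved.append(conf)
    return saved


def umatrix_bruteforce(weights):
    """Double-loop toroidal 8-neighbor average."""
    rows, cols, _ = weights.shape
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            total = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    total += np.linalg.norm(
                        weights[r, c] - weights[(r + dr) % rows, (c + dc) % cols]
                    )
            out[r, c] = total / 8.0
    return out


def simplex_least_squares(curves, obs):
    """Simplex-constrained weighted least squares (SLSQP), the reference
    solution the maximum-entropy fit approaches as theta -> 0."""
    m = curves.shape[0]
    sigma = obs.uncertainties if obs.uncertainties is not None else np.ones(
        len(obs.values)
    )
    ys = curves / sigma
    target = obs.values / sigma

    res = minimize(
        lambda w: float(np.sum((w @ ys - target) ** 2)),
        np.full(m, 1.0 / m),
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    return res.x


def conformations_equal(set_a, set_b, atol=1e-6):
    """Ordered bijection: same length, same atoms, coordinates within atol."""
    if len(set_a) != len(set_b):
        return False
    for x, y in zip(set_a, set_b):
        if list(x.names) != list(y.names) or list(x.resids) != list(y.resids):
            return False
        if not np.allclose(x.coords, y.coords, atol=atol):
            return False
    return True
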