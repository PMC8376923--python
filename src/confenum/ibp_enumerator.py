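"""Branch-and-prune enumeration of fragment conformations.

A fragment is a short stretch of the linker plus one dummy alanine at each
terminus (so that the first inner residue has a phi and the last inner
residue has a psi).  The conformational tree is explored depth-first:

* each inner residue's phi and psi boxes are converted to fourth-atom
  distance intervals, discretized into at most ``max_branches`` samples;
* each sampled distance yields up to two trilateration candidates (mirror
  images through the reference plane, i.e. the +tau / -tau branches), of
  which only those whose realized dihedral falls inside the torsion box
  are kept;
* the peptide omega torsion is fixed trans (180 deg), and carbonyl O and
  CB atoms are placed constructively (exact internal coordinates);
* every placement is checked sterically (scaled van-der-Waals) and each
  completed improper angle is verified; a failing branch is pruned with
  its subtree;
* a completed leaf is saved only if its CA RMSD to the previously saved
  conformation exceeds the save gate, and traversal stops at ``max_saved``.

Dummy residues participate in building and pruning but are stripped from
saved coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry_core import (
    AA1TO3,
    Conformation,
    ForceFieldParams,
    default_params,
    discretize_interval,
    distance_to_torsion,
    kabsch_superpose,
    measure_dihedral,
    place_atom,
    place_sp2_inplane,
    place_tetrahedral,
    torsion_to_distance,
    trilaterate,
)

__all__ = [
    "FragmentSpec",
    "EnumerationSettings",
    "EnumerationResult",
    "box_combinations",
    "enumerate_fragment",
    "run_fragment",
    "torsion_samples",
    "ca_rmsd",
]


@dataclass
class FragmentSpec:
    """Sequence and sampling boxes of one enumeration fragment.

    ``sequence`` covers the inner (non-dummy) residues only, numbered
    ``start_resid .. start_resid+len-1``; ``boxes`` maps each inner residue
    id to its list of candidate TorsionBox.  One dummy alanine is flagged
    at each terminus.
    """

    sequence: str
    start_resid: int
    boxes: dict
    dummy_resname: str = "ALA"

    def __post_init__(self):
        for rid in self.inner_resids():
            if rid not in self.boxes or not self.boxes[rid]:
                raise ValueError(f"inner residue {rid} has no torsion box")

    def inner_resids(self):
        return list(range(self.start_resid, self.start_resid + len(self.sequence)))

    @property
    def end_resid(self) -> int:
        return self.start_resid + len(self.sequence) - 1


@dataclass(frozen=True)
class EnumerationSettings:
    max_branches: int = 4
    min_step: float = 0.1          # A
    tolerance: float = 0.05        # A
    vdw_scale: float = 0.7
    improper_tol: float = 5.0      # deg
    save_rmsd_gate: float = 2.0    # A; <=0 disables the gate
    max_saved: int = 10 ** 9
    seed: int = 0
    gate_mode: str = "last"        # "last" or "all"

    def __post_init__(self):
        if self.max_saved < 1:
            raise ValueError("max_saved must be >= 1")
        if self.gate_mode not in ("last", "all"):
            raise ValueError("gate_mode must be 'last' or 'all'")


@dataclass
class EnumerationResult:
    conformations: list = field(default_factory=list)
    n_explored: int = 0
    n_pruned_steric: int = 0
    n_pruned_improper: int = 0
    n_saved: int = 0
    n_runs: int = 0
    complete: bool = True

    def merge(self, other: "EnumerationResult") -> "EnumerationResult":
        return EnumerationResult(
            self.conformations + other.conformations,
            self.n_explored + other.n_explored,
            self.n_pruned_steric + other.n_pruned_steric,
            self.n_pruned_improper + other.n_pruned_improper,
            self.n_saved + other.n_saved,
            self.n_runs + other.n_runs,
            self.complete and other.complete,
        )


def box_combinations(spec: FragmentSpec):
    """Cartesian product of per-residue box choices, each one iBP run."""
    rids = spec.inner_resids()
    for combo in itertools.product(*(spec.boxes[rid] for rid in rids)):
        yield dict(zip(rids, combo))


def ca_rmsd(conf_a: Conformation, conf_b: Conformation) -> float:
    """Best-fit CA RMSD between two conformations of the same length."""
    ca_a, ca_b = conf_a.ca_coords(), conf_b.ca_coords()
    if ca_a.shape != ca_b.shape:
        raise ValueError("conformations differ in CA count")
    n = ca_a.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        # two points: best fit aligns the segments, leaving half the
        # length difference at each end
        da = float(np.linalg.norm(ca_a[1] - ca_a[0]))
        db = float(np.linalg.norm(ca_b[1] - ca_b[0]))
        return abs(da - db) / 2.0
    _r, _t, rmsd = kabsch_superpose(ca_a, ca_b)
    return rmsd


# ---------------------------------------------------------------------------
# torsion interval -> distance samples -> signed torsion candidates
# ---------------------------------------------------------------------------

def _wrap180(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _abs_tau_range(lo: float, hi: float):
    """Range of |wrapped torsion| over the interval [lo, hi] (deg)."""
    if hi - lo >= 360.0:
        return 0.0, 180.0
    cands = [abs(_wrap180(lo)), abs(_wrap180(hi))]
    # interior extremes where the wrapped angle crosses 0 or +-180
    k0 = math.ceil(lo / 360.0)
    if lo <= 360.0 * k0 <= hi:
        cands.append(0.0)
    k1 = math.ceil((lo - 180.0) / 360.0)
    if lo <= 180.0 + 360.0 * k1 <= hi:
        cands.append(180.0)
    return min(cands), max(cands)


def _in_box(angle: float, lo: float, hi: float, slack: float) -> bool:
    """Is the wrapped angle within [lo, hi] extended by slack (circular)?"""
    width = (hi - lo) + 2 * slack
    if width >= 360.0:
        return True
    rel = (angle - (lo - slack)) % 360.0
    return rel <= width


def torsion_samples(lo: float, hi: float, kind: str, settings: EnumerationSettings,
                    params: ForceFieldParams):
    """Signed torsion candidates realized by interval-distance branching.

    Returns a list of lists: for each sampled distance (ascending), the
    signed torsion values (positive branch first) that fall inside the
    box.  This is the exact branching the enumerator performs, exposed so
    a Cartesian-construction oracle can replicate it.
    """
    t_min, t_max = _abs_tau_range(lo, hi)
    d_lo = torsion_to_distance(t_min, kind, params)
    d_hi = torsion_to_distance(t_max, kind, params)
    samples = discretize_interval(
        d_lo, d_hi, settings.max_branches, settings.min_step, settings.tolerance
    )
    # angular slack induced by the distance tolerance at the interval edges
    slack = 1e-6
    for d_edge, t_edge in ((d_lo, t_min), (d_hi, t_max)):
        for signum in (-1, 1):
            t = distance_to_torsion(d_edge + signum * settings.tolerance, kind, params)
            slack = max(slack, abs(t - t_edge) + 1e-6)
    out = []
    for d in samples:
        tau = distance_to_torsion(d, kind, params)
        signed = []
        for cand in (tau, -tau):
            # the mirror branch is distinct only for 0 < tau < 180
            if cand != tau and not (1e-9 < tau < 180.0 - 1e-9):
                continue
            if _in_box(cand, lo, hi, slack):
                signed.append(cand)
        out.append(signed)
    return out


# ---------------------------------------------------------------------------
# build plan
# ---------------------------------------------------------------------------

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


class _Plan:
    """Precomputed atom order, steric exclusions and improper schedule."""

    def __init__(self, spec: FragmentSpec, assignment, params: ForceFieldParams):
        self.spec = spec
        self.params = params
        self.assignment = assignment
        seq3 = (
            [spec.dummy_resname]
            + [AA1TO3.get(c.upper(), "ALA") for c in spec.sequence]
            + [spec.dummy_resname]
        )
        self.resids = list(
            range(spec.start_resid - 1, spec.start_resid + len(spec.sequence) + 1)
        )
        self.resnames = seq3
        self.n_res = len(seq3)
        # atom order: per residue i>=1: N_i, O_{i-1}, CA_i, C_i, CB_i
        self.atoms = []      # (resid_index, name)
        self.index = {}

        def add(i, name):
            self.index[(i, name)] = len(self.atoms)
            self.atoms.append((i, name))

        add(0, "N"); add(0, "CA"); add(0, "C")
        if seq3[0] != "GLY":
            add(0, "CB")
        for i in range(1, self.n_res):
            add(i, "N")
            add(i - 1, "O")
            add(i, "CA")
            add(i, "C")
            if seq3[i] != "GLY":
                add(i, "CB")
        self.n_atoms = len(self.atoms)
        self._steric_lists()
        self._improper_schedule()

    # --- steric -----------------------------------------------------------
    def _bond_graph(self):
        adj = [[] for _ in range(self.n_atoms)]

        def link(a, b):
            if a in self.index and b in self.index:
                ia, ib = self.index[a], self.index[b]
                adj[ia].append(ib)
                adj[ib].append(ia)

        for i in range(self.n_res):
            link((i, "N"), (i, "CA"))
            link((i, "CA"), (i, "C"))
            link((i, "C"), (i, "O"))
            link((i, "CA"), (i, "CB"))
            link((i, "C"), (i + 1, "N"))
        return adj

    def _steric_lists(self):
        adj = self._bond_graph()
        excluded = [set() for _ in range(self.n_atoms)]
        for a in range(self.n_atoms):
            for b in adj[a]:
                excluded[a].add(b)
                for c in adj[b]:
                    if c != a:
                        excluded[a].add(c)
        radii = np.array(
            [self.params.radius(_ELEMENT[name]) for _i, name in self.atoms]
        )
        self.check_against = []
        self.check_limits = []
        for k in range(self.n_atoms):
            earlier = [j for j in range(k) if j not in excluded[k]]
            self.check_against.append(np.array(earlier, dtype=int))
            self.check_limits.append(radii[k] + radii[earlier])

    # --- impropers --------------------------------------------------------
    def _improper_schedule(self):
        """Impropers keyed by the build index at which they become complete."""
        self.impropers_at = {}
        for i in range(self.n_res):
            quad_cb = [(i, "CB"), (i, "N"), (i, "CA"), (i, "C")]
            if all(k in self.index for k in quad_cb):
                idxs = [self.index[k] for k in quad_cb]
                last = max(idxs)
                self.impropers_at.setdefault(last, []).append(
                    (idxs, self.params.impropers["CA_CHIRALITY"])
                )
            quad_o = [(i, "O"), (i, "CA"), (i, "C"), (i + 1, "N")]
            if all(k in self.index for k in quad_o):
                idxs = [self.index[k] for k in quad_o]
                last = max(idxs)
                self.impropers_at.setdefault(last, []).append(
                    (idxs, self.params.impropers["CARBONYL_PLANARITY"])
                )

    # --- leaf -------------------------------------------------------------
    def leaf_conformation(self, coords: np.ndarray) -> Conformation:
        keep = [
            self.index[(i, name)]
            for i in range(1, self.n_res - 1)
            for name in ("N", "CA", "C", "O", "CB")
            if (i, name) in self.index
        ]
        resids = np.array([self.resids[self.atoms[k][0]] for k in keep])
        resnames = [self.resnames[self.atoms[k][0]] for k in keep]
        names = [self.atoms[k][1] for k in keep]
        elements = [_ELEMENT[n] for n in names]
        return Conformation(
            resids, resnames, names, elements, coords[keep].copy(),
            self.spec.sequence.upper(),
        )


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def enumerate_fragment(
    spec: FragmentSpec,
    assignment,
    settings: EnumerationSettings | None = None,
    params: ForceFieldParams | None = None,
) -> EnumerationResult:
    """Depth-first enumeration of one box assignment (one iBP run)."""
    settings = settings or EnumerationSettings()
    params = params or default_params()
    plan = _Plan(spec, assignment, params)
    result = EnumerationResult(n_runs=1)
    coords = np.zeros((plan.n_atoms, 3))

    b_nca = params.bond("N", "CA")
    b_cac = params.bond("CA", "C")
    b_cn = params.bond("C", "N")
    a_ncac = params.angle("N", "CA", "C")
    a_cacn = params.angle("CA", "C", "N")
    a_cnca = params.angle("C", "N", "CA")

    def two_bond(b1, b2, angle_deg):
        a = math.radians(angle_deg)
        return math.sqrt(b1 * b1 + b2 * b2 - 2 * b1 * b2 * math.cos(a))

    d_ca_nnext = two_bond(b_cac, b_cn, a_cacn)   # CA(i)...N(i+1)
    d_n_cnext = two_bond(b_nca, b_cac, a_ncac)   # N(i)...C(i)

    # canonical root
    coords[plan.index[(0, "N")]] = (0.0, 0.0, 0.0)
    coords[plan.index[(0, "CA")]] = (b_nca, 0.0, 0.0)
    ang = math.radians(a_ncac)
    coords[plan.index[(0, "C")]] = coords[plan.index[(0, "CA")]] + b_cac * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )

    gate = settings.save_rmsd_gate
    saved_for_gate = []

    def checks_ok(k) -> bool:
        """Steric + improper checks for the atom at build index k."""
        result.n_explored += 1
        earlier = plan.check_against[k]
        if earlier.size:
            d = np.linalg.norm(coords[earlier] - coords[k], axis=1)
            if (d < settings.vdw_scale * plan.check_limits[k]).any():
                result.n_pruned_steric += 1
                return False
        for idxs, target in plan.impropers_at.get(k, ()):
            measured = measure_dihedral(*(coords[j] for j in idxs))
            if _angdiff(measured, target) > settings.improper_tol:
                result.n_pruned_improper += 1
                return False
        return True

    def place_exact(k, i, name) -> bool:
        """Constructive (single-candidate) placement; False on prune."""
        if name == "CB":
            coords[k] = place_tetrahedral(
                coords[plan.index[(i, "CA")]],
                coords[plan.index[(i, "N")]],
                coords[plan.index[(i, "C")]],
                params.bond("CA", "CB"),
                params.angle("N", "CA", "CB"),
                params.angle("C", "CA", "CB"),
                sign=1,
            )
        elif name == "O":
            coords[k] = place_sp2_inplane(
                coords[plan.index[(i, "C")]],
                coords[plan.index[(i, "CA")]],
                coords[plan.index[(i + 1, "N")]],
                params.bond("C", "O"),
                params.angle("CA", "C", "O"),
            )
        elif name == "CA":
            coords[k] = place_atom(
                coords[plan.index[(i - 1, "CA")]],
                coords[plan.index[(i - 1, "C")]],
                coords[plan.index[(i, "N")]],
                b_nca, a_cnca, 180.0,   # omega fixed trans
            )
        else:
            raise AssertionError(name)
        return checks_ok(k)

    def torsion_branches(i, name):
        """(refs, exact distances, per-sample signed torsion candidates)."""
        if name == "N":
            # psi of residue i-1: quad N(i-1)-CA(i-1)-C(i-1)-N(i)
            quad = [
                plan.index[(i - 1, "N")],
                plan.index[(i - 1, "CA")],
                plan.index[(i - 1, "C")],
            ]
            kind = "psi"
            exact = (d_ca_nnext, b_cn)
            rid = plan.resids[i - 1]
            inner = 1 <= i - 1 <= plan.n_res - 2
            box = assignment.get(rid) if inner else None
            lo, hi = (box.psi_lo, box.psi_hi) if box else (180.0, 180.0)
        else:  # name == "C": phi of residue i: quad C(i-1)-N(i)-CA(i)-C(i)
            quad = [
                plan.index[(i - 1, "C")],
                plan.index[(i, "N")],
                plan.index[(i, "CA")],
            ]
            kind = "phi"
            exact = (d_n_cnext, b_cac)
            rid = plan.resids[i]
            inner = 1 <= i <= plan.n_res - 2
            box = assignment.get(rid) if inner else None
            lo, hi = (box.phi_lo, box.phi_hi) if box else (180.0, 180.0)
        per_sample = torsion_samples(lo, hi, kind, settings, params)
        return quad, kind, exact, per_sample

    def descend(k: int) -> bool:
        """Returns False when the save cap was hit (abort traversal)."""
        if k == plan.n_atoms:
            leaf = plan.leaf_conformation(coords)
            if gate > 0 and saved_for_gate:
                pool = (
                    saved_for_gate
                    if settings.gate_mode == "all"
                    else saved_for_gate[-1:]
                )
                if any(ca_rmsd(leaf, prev) <= gate for prev in pool):
                    return True
            result.conformations.append(leaf)
            saved_for_gate.append(leaf)
            result.n_saved += 1
            if result.n_saved >= settings.max_saved:
                result.complete = False
                return False
            return True
        i, name = plan.atoms[k]
        if name in ("CB", "O", "CA"):
            if place_exact(k, i, name):
                return descend(k + 1)
            return True
        # interval-torsion atom (N via psi, C via phi)
        quad, kind, (d_far, d_bond), per_sample = torsion_branches(i, name)
        p1, p2, p3 = coords[quad[0]], coords[quad[1]], coords[quad[2]]
        for signed_taus in per_sample:
            if not signed_taus:
                continue
            d_sample = torsion_to_distance(abs(signed_taus[0]), kind, params)
            candidates = trilaterate((p1, p2, p3), d_sample, d_far, d_bond)
            # order candidates by realized dihedral: positive branch first
            measured = [
                (measure_dihedral(p1, p2, p3, c), c) for c in candidates
            ]
            measured.sort(key=lambda mc: -mc[0])
            wanted = list(signed_taus)
            for tau_m, cand in measured:
                match = None
                for t in wanted:
                    if _angdiff(tau_m, t) < 1e-3:
                        match = t
                        break
                if match is None:
                    continue
                wanted.remove(match)
                coords[k] = cand
                if checks_ok(k):
                    if not descend(k + 1):
                        return False
        return True

    # atoms 0..2 are the canonical root triple; search from index 3
    descend(3)
    return result


def run_fragment(
    spec: FragmentSpec,
    settings: EnumerationSettings | None = None,
    params: ForceFieldParams | None = None,
) -> EnumerationResult:
    """Enumerate every box assignment and merge results.

    ``n_runs`` on the merged result is the number of assignments executed
    (the per-fragment count of iBP runs); conformation counts accumulate.
    """
    merged = EnumerationResult(n_runs=0)
    for assignment in box_combinations(spec):
        merged = merged.merge(enumerate_fragment(spec, assignment, settings, params))
    return merged
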