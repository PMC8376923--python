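"""Internal-coordinate geometry for backbone enumeration.

Provides the primitives the branch-and-prune enumerator is built on:
conversion between backbone torsion angles and the equivalent fourth-atom
distances, trilateration of new atom positions from three placed reference
atoms, interval discretization for tree branching, steric and improper-angle
pruning checks, and Kabsch superposition.

The backbone dihedral phi (C(i-1)-N-CA-C) fixes the C(i-1)...C(i) distance
and psi (N-CA-C-N(i+1)) fixes the N(i)...N(i+1) distance once bond lengths
and bond angles are held at their parameter-table values; this equivalence
is what lets a torsion interval act as a distance interval during
trilateration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceFieldParams",
    "Conformation",
    "BuildOrder",
    "BuildStep",
    "default_params",
    "load_params",
    "torsion_to_distance",
    "distance_to_torsion",
    "trilaterate",
    "discretize_interval",
    "steric_ok",
    "improper_ok",
    "kabsch_superpose",
    "place_atom",
    "place_tetrahedral",
    "place_sp2_inplane",
    "build_backbone",
    "measure_dihedral",
    "backbone_bonds",
    "AA1TO3",
    "AA3TO1",
]

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}


class GeometryError(ValueError):
    """Raised on degenerate or unparameterized geometric input."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceFieldParams:
    """Bond lengths (A), bond angles (deg), improper targets (deg) and
    van-der-Waals radii (A) for backbone + CB building.

    Keys are atom-name pairs/triples along the covalent path; lookups are
    direction-insensitive for bonds. Radii are keyed by element symbol.
    """

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    impropers: dict = field(default_factory=dict)
    vdw: dict = field(default_factory=dict)

    def bond(self, a: str, b: str) -> float:
        try:
            return self.bonds[(a, b)] if (a, b) in self.bonds else self.bonds[(b, a)]
        except KeyError:
            raise GeometryError(f"no bond length for {a}-{b}") from None

    def angle(self, a: str, b: str, c: str) -> float:
        try:
            return (
                self.angles[(a, b, c)]
                if (a, b, c) in self.angles
                else self.angles[(c, b, a)]
            )
        except KeyError:
            raise GeometryError(f"no bond angle for {a}-{b}-{c}") from None

    def radius(self, element: str) -> float:
        try:
            return self.vdw[element]
        except KeyError:
            raise GeometryError(f"unparameterized atom element {element!r}")


_DEFAULT_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}
_DEFAULT_ANGLES = {
    ("C", "N", "CA"): 121.7,
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,
    ("CA", "C", "O"): 120.8,
    ("O", "C", "N"): 123.0,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
}
# Radii for heavy backbone atoms; the enumerator scales them (default 0.7)
# before clash checks.
_DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52}


def _ideal_improper_targets(bonds, angles):
    """Improper-angle targets measured on an ideally built residue.

    CA chirality: dihedral CB-N-CA-C; the L configuration is the positive
    out-of-plane branch of the tetrahedral solve.  Carbonyl planarity:
    dihedral O-CA-C-N(i+1) = 180 (O and the next amide N trans across C).
    """
    n = np.zeros(3)
    ca = n + np.array([bonds[("N", "CA")], 0.0, 0.0])
    # C in the xy-plane
    ang = math.radians(angles[("N", "CA", "C")])
    c = ca + bonds[("CA", "C")] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    cb = place_tetrahedral(
        ca, n, c, bonds[("CA", "CB")],
        angles[("N", "CA", "CB")], angles[("C", "CA", "CB")], sign=1,
    )
    chi = measure_dihedral(cb, n, ca, c)
    return {"CA_CHIRALITY": chi, "CARBONYL_PLANARITY": 180.0}


def default_params() -> ForceFieldParams:
    """Standard protein heavy-atom geometry (Engh–Huber-type values)."""
    impropers = _ideal_improper_targets(_DEFAULT_BONDS, _DEFAULT_ANGLES)
    return ForceFieldParams(
        bonds=dict(_DEFAULT_BONDS),
        angles=dict(_DEFAULT_ANGLES),
        impropers=impropers,
        vdw=dict(_DEFAULT_VDW),
    )


def load_params(path) -> ForceFieldParams:
    """Read a plain-text parameter file.

    Sections are introduced by ``[bonds]``, ``[angles]``, ``[impropers]``,
    ``[vdw]``; each line is atom names followed by a value, ``#`` comments.
    Entries override the built-in defaults.
    """
    params = default_params()
    bonds = dict(params.bonds)
    angles = dict(params.angles)
    impropers = dict(params.impropers)
    vdw = dict(params.vdw)
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].lower()
                continue
            parts = line.split()
            try:
                value = float(parts[-1])
            except ValueError:
                raise GeometryError(f"{path}:{lineno}: bad value {parts[-1]!r}")
            keys = tuple(parts[:-1])
            if section == "bonds" and len(keys) == 2:
                bonds[keys] = value
            elif section == "angles" and len(keys) == 3:
                angles[keys] = value
            elif section == "impropers" and len(keys) == 1:
                impropers[keys[0]] = value
            elif section == "vdw" and len(keys) == 1:
                vdw[keys[0]] = value
            else:
                raise GeometryError(f"{path}:{lineno}: malformed line {raw!r}")
    return ForceFieldParams(bonds=bonds, angles=angles, impropers=impropers, vdw=vdw)


# ---------------------------------------------------------------------------
# conformation container
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    """Ordered atom records with Cartesian coordinates in Angstrom."""

    resids: np.ndarray          # (n,) int
    resnames: list
    names: list
    elements: list
    coords: np.ndarray          # (n, 3) float
    sequence: str = ""

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.resids), 3):
            raise ValueError("coords/resids length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.resids)

    def copy(self) -> "Conformation":
        return Conformation(
            self.resids.copy(), list(self.resnames), list(self.names),
            list(self.elements), self.coords.copy(), self.sequence,
        )

    def index_of(self, resid: int, name: str) -> int:
        for i in range(self.n_atoms):
            if self.resids[i] == resid and self.names[i] == name:
                return i
        raise KeyError(f"atom {name} of residue {resid} not present")

    def ca_mask(self) -> np.ndarray:
        return np.array([nm == "CA" for nm in self.names])

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.ca_mask()]

    def ca_resids(self) -> np.ndarray:
        return self.resids[self.ca_mask()]

    def select_resids(self, keep) -> "Conformation":
        keep = set(int(r) for r in keep)
        mask = np.array([int(r) in keep for r in self.resids])
        seq = "".join(
            AA3TO1.get(rn, "X")
            for rn, r, nm in zip(self.resnames, self.resids, self.names)
            if int(r) in keep and nm == "CA"
        )
        return Conformation(
            self.resids[mask],
            [rn for rn, m in zip(self.resnames, mask) if m],
            [nm for nm, m in zip(self.names, mask) if m],
            [el for el, m in zip(self.elements, mask) if m],
            self.coords[mask],
            seq,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def residue_ids(self) -> np.ndarray:
        seen, out = set(), []
        for r in self.resids:
            if int(r) not in seen:
                seen.add(int(r))
                out.append(int(r))
        return np.array(out)


@dataclass(frozen=True)
class BuildStep:
    """One atom placement of a build order.

    ``refs`` are indices of three already-placed atoms; ``interval`` marks
    which of the three trilateration distances (0, 1 or 2) is an interval,
    or None when all three are exact.
    """

    atom: int
    refs: tuple
    interval: int | None = None


@dataclass
class BuildOrder:
    steps: list

    def __post_init__(self):
        placed = {0, 1, 2}
        for st in self.steps:
            if len(st.refs) != 3 or any(r not in placed for r in st.refs):
                raise ValueError(f"step for atom {st.atom} references unplaced atoms")
            placed.add(st.atom)


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def measure_angle(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, IUPAC sign convention."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.degrees(math.atan2(y, x))


_TORSION_QUADS = {
    # (atom names of the dihedral quad); bond/angle lookups run along it
    "phi": ("C", "N", "CA", "C"),
    "psi": ("N", "CA", "C", "N"),
}


def _torsion_coeffs(kind: str, params: ForceFieldParams):
    try:
        a, b, c, d = _TORSION_QUADS[kind]
    except KeyError:
        raise GeometryError(f"unsupported torsion kind {kind!r}") from None
    b1 = params.bond(a, b)
    b2 = params.bond(b, c)
    b3 = params.bond(c, d)
    t1 = math.radians(params.angle(a, b, c))
    t2 = math.radians(params.angle(b, c, d))
    q = (
        b1 * b1 + b2 * b2 + b3 * b3
        - 2 * b1 * b2 * math.cos(t1)
        - 2 * b2 * b3 * math.cos(t2)
        + 2 * b1 * b3 * math.cos(t1) * math.cos(t2)
    )
    r = -2 * b1 * b3 * math.sin(t1) * math.sin(t2)
    return q, r


def torsion_to_distance(angle: float, kind: str, params: ForceFieldParams) -> float:
    """Distance between the 1st and 4th atoms of the phi/psi dihedral quad.

    d^2 is affine in cos(angle), so d depends on |angle| only and grows
    strictly with it (trans is farthest).  The half-angle form
    d^2 = d(0)^2 + (d(180)^2 - d(0)^2) sin^2(angle/2) is used so the
    inverse round-trips to full precision at the interval ends.
    """
    q, r = _torsion_coeffs(kind, params)
    d0_sq, d180_sq = q + r, q - r
    s = math.sin(math.radians(angle) / 2.0)
    return math.sqrt(max(d0_sq + (d180_sq - d0_sq) * s * s, 0.0))


def distance_to_torsion(distance: float, kind: str, params: ForceFieldParams) -> float:
    """Inverse of :func:`torsion_to_distance`; returns |angle| in degrees."""
    q, r = _torsion_coeffs(kind, params)
    d0_sq, d180_sq = q + r, q - r
    x = (distance * distance - d0_sq) / (d180_sq - d0_sq)
    return math.degrees(2.0 * math.asin(math.sqrt(max(0.0, min(1.0, x)))))


def trilaterate(ref_positions, d1: float, d2: float, d3: float, tol: float = 1e-9):
    """Intersect three spheres centered on the reference atoms.

    Returns 0, 1, or 2 candidate points; the two-solution case lists the
    candidate on the positive side of the reference plane first, and the
    candidates are mirror images through that plane.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in ref_positions)
    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d < 1e-12:
        raise GeometryError("degenerate trilateration: coincident references")
    ex = ex / d
    v3 = p3 - p1
    i = np.dot(ex, v3)
    ey = v3 - i * ex
    j = np.linalg.norm(ey)
    if j < 1e-9:
        raise GeometryError("degenerate trilateration: collinear references")
    ey = ey / j
    ez = np.cross(ex, ey)
    x = (d1 * d1 - d2 * d2 + d * d) / (2 * d)
    y = (d1 * d1 - d3 * d3 + i * i + j * j - 2 * i * x) / (2 * j)
    z2 = d1 * d1 - x * x - y * y
    scale = max(1.0, d1 * d1)
    if z2 < -tol * scale:
        return []
    if z2 <= tol * scale:
        return [p1 + x * ex + y * ey]
    z = math.sqrt(z2)
    return [p1 + x * ex + y * ey + z * ez, p1 + x * ex + y * ey - z * ez]


def discretize_interval(
    lo: float,
    hi: float,
    max_branches: int = 4,
    min_step: float = 0.1,
    tolerance: float = 0.05,
):
    """Sample an interval distance for tree branching.

    The interval is first widened by ``tolerance`` on both sides; the number
    of samples is capped at ``max_branches`` and floored so that no
    sub-interval is narrower than ``min_step``; samples sit at sub-interval
    midpoints.
    """
    if lo > hi:
        raise ValueError("interval lower bound exceeds upper bound")
    a, b = lo - tolerance, hi + tolerance
    width = b - a
    n = min(max_branches, max(1, int(math.floor(width / min_step + 1e-9))))
    step = width / n
    return [a + (k + 0.5) * step for k in range(n)]


# ---------------------------------------------------------------------------
# pruning checks
# ---------------------------------------------------------------------------

def backbone_bonds(conf: Conformation):
    """Covalent bond list inferred from backbone atom naming."""
    bonds = []
    idx = {}
    for i in range(conf.n_atoms):
        idx[(int(conf.resids[i]), conf.names[i])] = i
    for rid in conf.residue_ids():
        rid = int(rid)
        for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
            if (rid, a) in idx and (rid, b) in idx:
                bonds.append((idx[(rid, a)], idx[(rid, b)]))
        if (rid, "C") in idx and (rid + 1, "N") in idx:
            bonds.append((idx[(rid, "C")], idx[(rid + 1, "N")]))
    return bonds


def _exclusion_pairs(conf: Conformation):
    """Atom pairs separated by <=2 bonds (never clash-checked)."""
    n = conf.n_atoms
    adj = [[] for _ in range(n)]
    for a, b in backbone_bonds(conf):
        adj[a].append(b)
        adj[b].append(a)
    excl = set()
    for a in range(n):
        for b in adj[a]:
            excl.add((min(a, b), max(a, b)))
            for c in adj[b]:
                if c != a:
                    excl.add((min(a, c), max(a, c)))
    return excl


def steric_ok(conf: Conformation, params: ForceFieldParams, scale: float = 0.7) -> bool:
    """True iff no non-excluded atom pair is closer than scale*(ri+rj)."""
    n = conf.n_atoms
    if n < 2:
        return True
    radii = np.array([params.radius(el) for el in conf.elements])
    excl = _exclusion_pairs(conf)
    diff = conf.coords[:, None, :] - conf.coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    limit = scale * (radii[:, None] + radii[None, :])
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            if dist[i, j] < limit[i, j]:
                return False
    return True


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def improper_impropers(conf: Conformation, params: ForceFieldParams):
    """Yield (label, measured, target) for every defined improper."""
    idx = {}
    for i in range(conf.n_atoms):
        idx[(int(conf.resids[i]), conf.names[i])] = i
    for rid in conf.residue_ids():
        rid = int(rid)
        keys = [(rid, "CB"), (rid, "N"), (rid, "CA"), (rid, "C")]
        if all(k in idx for k in keys):
            pts = [conf.coords[idx[k]] for k in keys]
            yield (
                f"CA_CHIRALITY:{rid}",
                measure_dihedral(*pts),
                params.impropers["CA_CHIRALITY"],
            )
        keys = [(rid, "O"), (rid, "CA"), (rid, "C"), (rid + 1, "N")]
        if all(k in idx for k in keys):
            pts = [conf.coords[idx[k]] for k in keys]
            yield (
                f"CARBONYL_PLANARITY:{rid}",
                measure_dihedral(*pts),
                params.impropers["CARBONYL_PLANARITY"],
            )


def improper_ok(conf: Conformation, params: ForceFieldParams, tol_deg: float = 5.0) -> bool:
    """True iff every defined improper is within tol_deg of its target."""
    for _label, measured, target in improper_impropers(conf, params):
        if _angdiff(measured, target) > tol_deg:
            return False
    return True


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, target):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) such that ``mobile @ rotation.T + translation`` best fits
    ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise GeometryError("underdetermined superposition: need >=3 matched points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = math.sqrt(((moved - target) ** 2).sum() / mobile.shape[0])
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# constructive placement (exact internal coordinates)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from placed atoms a-b-c with bond |c-D|, angle b-c-D and
    dihedral a-b-c-D (degrees) — the natural-extension reference frame."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    # minus on the out-of-plane term gives the IUPAC dihedral sign
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), -math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_tetrahedral(center, ref1, ref2, bond, angle1, angle2, sign=1) -> np.ndarray:
    """Place an atom at ``bond`` from ``center`` forming ``angle1`` with
    center->ref1 and ``angle2`` with center->ref2; ``sign`` selects the
    out-of-plane branch (+1 = L-amino-acid CB)."""
    center = np.asarray(center, dtype=float)
    u1 = np.asarray(ref1, dtype=float) - center
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.asarray(ref2, dtype=float) - center
    u2 = u2 / np.linalg.norm(u2)
    c1 = math.cos(math.radians(angle1))
    c2 = math.cos(math.radians(angle2))
    dot = np.dot(u1, u2)
    det = 1.0 - dot * dot
    if det < 1e-12:
        raise GeometryError("degenerate tetrahedral placement")
    a = (c1 - c2 * dot) / det
    b = (c2 - c1 * dot) / det
    w2 = 1.0 - (a * a + b * b + 2 * a * b * dot)
    if w2 < 0.0:
        w2 = 0.0
    n = np.cross(u1, u2)
    n = n / np.linalg.norm(n)
    u = a * u1 + b * u2 + sign * math.sqrt(w2) * n
    return center + bond * u


def place_sp2_inplane(center, ref1, ref2, bond, angle_from_ref1) -> np.ndarray:
    """Place an sp2 substituent in the plane (ref1, center, ref2) at
    ``angle_from_ref1`` from center->ref1, on the side opposite ref2."""
    center = np.asarray(center, dtype=float)
    u1 = np.asarray(ref1, dtype=float) - center
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.asarray(ref2, dtype=float) - center
    u2 = u2 / np.linalg.norm(u2)
    # in-plane unit vector perpendicular to u1, pointing away from u2
    perp = u2 - np.dot(u2, u1) * u1
    np_ = np.linalg.norm(perp)
    if np_ < 1e-12:
        raise GeometryError("degenerate sp2 placement")
    perp = perp / np_
    ang = math.radians(angle_from_ref1)
    u = math.cos(ang) * u1 - math.sin(ang) * perp
    return center + bond * u


# ---------------------------------------------------------------------------
# direct chain construction
# ---------------------------------------------------------------------------

def build_backbone(
    sequence: str,
    torsions,
    params: ForceFieldParams | None = None,
    omega: float = 180.0,
    start_resid: int = 1,
    with_o: bool = True,
    with_cb: bool = True,
) -> Conformation:
    """Build a peptide backbone (N, CA, C [, O, CB]) from phi/psi values.

    ``torsions[i] = (phi_i, psi_i)`` in degrees; the first residue's phi and
    the last residue's psi are not realizable in a finite chain and are
    ignored.  The last residue carries no carbonyl O (its placement needs
    the next amide N).  Glycine gets no CB.  Used both by the synthetic
    generator and as the independent Cartesian oracle for the enumerator.
    """
    if params is None:
        params = default_params()
    seq = sequence.upper()
    m = len(seq)
    if len(torsions) != m:
        raise ValueError("torsions length must match sequence length")
    n_pos = [None] * m
    ca_pos = [None] * m
    c_pos = [None] * m
    # canonical first residue
    n_pos[0] = np.zeros(3)
    ca_pos[0] = np.array([params.bond("N", "CA"), 0.0, 0.0])
    ang = math.radians(params.angle("N", "CA", "C"))
    c_pos[0] = ca_pos[0] + params.bond("CA", "C") * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, m):
        psi_prev = torsions[i - 1][1]
        n_pos[i] = place_atom(
            n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
            params.bond("C", "N"), params.angle("CA", "C", "N"), psi_prev,
        )
        ca_pos[i] = place_atom(
            ca_pos[i - 1], c_pos[i - 1], n_pos[i],
            params.bond("N", "CA"), params.angle("C", "N", "CA"), omega,
        )
        phi = torsions[i][0]
        c_pos[i] = place_atom(
            c_pos[i - 1], n_pos[i], ca_pos[i],
            params.bond("CA", "C"), params.angle("N", "CA", "C"), phi,
        )
    resids, resnames, names, elements, coords = [], [], [], [], []
    for i, one in enumerate(seq):
        res3 = AA1TO3.get(one, "ALA")
        rid = start_resid + i

        def add(name, el, pos):
            resids.append(rid)
            resnames.append(res3)
            names.append(name)
            elements.append(el)
            coords.append(pos)

        add("N", "N", n_pos[i])
        add("CA", "C", ca_pos[i])
        add("C", "C", c_pos[i])
        if with_o and i + 1 < m:
            o = place_sp2_inplane(
                c_pos[i], ca_pos[i], n_pos[i + 1],
                params.bond("C", "O"), params.angle("CA", "C", "O"),
            )
            add("O", "O", o)
        if with_cb and res3 != "GLY":
            cb = place_tetrahedral(
                ca_pos[i], n_pos[i], c_pos[i],
                params.bond("CA", "CB"),
                params.angle("N", "CA", "CB"), params.angle("C", "CA", "CB"),
                sign=1,
            )
            add("CB", "C", cb)
    return Conformation(
        np.array(resids), resnames, names, elements, np.array(coords), seq
    )
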