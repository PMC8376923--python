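"""Attachment of rigid folded domains to enumerated linker conformations.

The first domain is attached by a grid search: candidate positions for the
domain's geometric center are lattice points around the linker (bounding
box of the linker CA atoms padded by the domain's radius of gyration),
kept when closer than R_g to the CA of the downstream anchor residue and
farther than 2 A from every linker CA.  At each candidate the domain is
rotated so that its anchor-to-anchor vector aligns with the linker's, then
translated by the mean of the two anchor displacement vectors,
T = (V_a + V_b)/2.  A pose is accepted when fewer than 3 cross CA pairs
clash below 1 A and the mean of the two anchor CA-CA distances is below
6 A.

The second domain rides a reference complex: the complex is superposed
onto the partial model over a stated backbone residue range, the second
domain is translated by the bridge-residue CA displacement, and the
result is kept when fewer than 50 atoms clash below 1 A across the
junction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .geometry_core import Conformation, GeometryError, kabsch_superpose

__all__ = [
    "AttachmentSpec",
    "SecondDomainSpec",
    "gyration_radius",
    "candidate_grid",
    "rotation_between",
    "place_domain",
    "search_placements",
    "merge_domain_linker",
    "attach_second_domain",
]


@dataclass(frozen=True)
class AttachmentSpec:
    """Grid-search acceptance rules for the first domain."""

    anchor_a: int                # shared residue ids (domain C-terminal tail
    anchor_b: int                # = linker N-terminal stretch)
    grid_exclusion: float = 2.0  # A; grid point must be farther from every linker CA
    clash_distance: float = 1.0  # A
    max_ca_clashes: int = 3      # accepted iff strictly fewer
    max_anchor_distance: float = 6.0  # A, mean over the two anchor CA pairs

    def __post_init__(self):
        if not self.anchor_a < self.anchor_b:
            raise ValueError("anchor residues must satisfy a < b")


@dataclass(frozen=True)
class SecondDomainSpec:
    """Superposition range and clash rule for the second domain."""

    superpose_lo: int
    superpose_hi: int
    bridge_residue: int
    first_range: tuple
    second_range: tuple
    clash_distance: float = 1.0
    max_atom_clashes: int = 50   # accepted iff strictly fewer


def gyration_radius(conf: Conformation, mass_weighted: bool = True) -> float:
    """Root-mean-square (optionally mass-weighted) distance from centroid."""
    masses = {"C": 12.011, "N": 14.007, "O": 15.999}
    if mass_weighted:
        m = np.array([masses.get(el, 12.0) for el in conf.elements])
    else:
        m = np.ones(conf.n_atoms)
    center = (conf.coords * m[:, None]).sum(axis=0) / m.sum()
    sq = ((conf.coords - center) ** 2).sum(axis=1)
    return math.sqrt((m * sq).sum() / m.sum())


def candidate_grid(
    linker: Conformation,
    spec: AttachmentSpec,
    r_g: float,
    spacing: float = 2.0,
) -> np.ndarray:
    """Lattice of candidate domain-center positions around the linker.

    The lattice spans the linker CA bounding box padded by r_g per axis;
    points are kept iff strictly closer than r_g to the CA of anchor_b and
    strictly farther than the exclusion distance from every linker CA.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    ca = linker.ca_coords()
    anchor_ca = linker.coords[linker.index_of(spec.anchor_b, "CA")]
    lo = ca.min(axis=0) - r_g
    hi = ca.max(axis=0) + r_g
    axes = [np.arange(lo[k], hi[k] + spacing / 2, spacing) for k in range(3)]
    pts = np.array(list(itertools.product(*axes)))
    d_anchor = np.linalg.norm(pts - anchor_ca, axis=1)
    d_ca = np.linalg.norm(pts[:, None, :] - ca[None, :, :], axis=2).min(axis=1)
    keep = (d_anchor < r_g) & (d_ca > spec.grid_exclusion)
    out = pts[keep]
    if out.shape[0] == 0:
        raise GeometryError("no candidate placements on the grid")
    return out


def rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation matrix mapping unit(v_from) to unit(v_to)."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise GeometryError("degenerate anchors: zero-length anchor vector")
    a, b = a / na, b / nb
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # anti-parallel: 180 deg about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def place_domain(
    domain: Conformation,
    linker: Conformation,
    grid_point,
    spec: AttachmentSpec,
    spin_angle: float = 0.0,
):
    """One grid-search placement of the domain against the linker.

    The domain centroid is moved to the grid point, the domain is rotated
    so its anchor vector (CA(a) -> CA(b)) aligns with the linker's, spun by
    ``spin_angle`` (deg) about that vector (the alignment leaves this
    degree of freedom open), then translated by the mean anchor
    displacement T.  Returns (placed domain, accepted, diagnostics).
    """
    grid_point = np.asarray(grid_point, dtype=float)
    centered = domain.transformed(np.eye(3), -domain.coords.mean(axis=0))
    moved = centered.transformed(np.eye(3), grid_point)

    v_dom = (
        moved.coords[moved.index_of(spec.anchor_b, "CA")]
        - moved.coords[moved.index_of(spec.anchor_a, "CA")]
    )
    v_lnk = (
        linker.coords[linker.index_of(spec.anchor_b, "CA")]
        - linker.coords[linker.index_of(spec.anchor_a, "CA")]
    )
    rot = rotation_between(v_dom, v_lnk)
    if spin_angle:
        rot = _axis_rotation(v_lnk, math.radians(spin_angle)) @ rot
    center = moved.coords.mean(axis=0)
    placed = moved.transformed(rot, center - rot @ center)

    v_a = (
        linker.coords[linker.index_of(spec.anchor_a, "CA")]
        - placed.coords[placed.index_of(spec.anchor_a, "CA")]
    )
    v_b = (
        linker.coords[linker.index_of(spec.anchor_b, "CA")]
        - placed.coords[placed.index_of(spec.anchor_b, "CA")]
    )
    t = 0.5 * (v_a + v_b)
    placed = placed.transformed(np.eye(3), t)

    # acceptance
    d_a = np.linalg.norm(
        placed.coords[placed.index_of(spec.anchor_a, "CA")]
        - linker.coords[linker.index_of(spec.anchor_a, "CA")]
    )
    d_b = np.linalg.norm(
        placed.coords[placed.index_of(spec.anchor_b, "CA")]
        - linker.coords[linker.index_of(spec.anchor_b, "CA")]
    )
    ca_d = placed.ca_coords()
    ca_l = linker.ca_coords()
    cross = np.linalg.norm(ca_d[:, None, :] - ca_l[None, :, :], axis=2)
    n_clash = int((cross < spec.clash_distance).sum())
    mean_anchor = float(0.5 * (d_a + d_b))
    accepted = bool(
        n_clash < spec.max_ca_clashes and mean_anchor < spec.max_anchor_distance
    )
    return placed, accepted, {"n_ca_clashes": n_clash, "mean_anchor_distance": mean_anchor}


def search_placements(
    domain: Conformation,
    linker: Conformation,
    spec: AttachmentSpec,
    spacing: float = 2.0,
    n_spin: int = 8,
):
    """Grid search over candidate centers and spin angles; all accepted poses."""
    r_g = gyration_radius(domain)
    try:
        grid = candidate_grid(linker, spec, r_g, spacing)
    except GeometryError:
        return []
    accepted = []
    for pt in grid:
        for k in range(max(1, n_spin)):
            spin = 360.0 * k / max(1, n_spin)
            placed, ok, diag = place_domain(domain, linker, pt, spec, spin)
            if ok:
                accepted.append((placed, diag))
    return accepted


def merge_domain_linker(
    domain: Conformation, linker: Conformation, split_residue: int
) -> Conformation:
    """Single chain: residues <= split from the domain, > split from linker."""
    dom_ids = [int(r) for r in domain.residue_ids() if r <= split_residue]
    lnk_ids = [int(r) for r in linker.residue_ids() if r > split_residue]
    if not dom_ids or not lnk_ids:
        raise ValueError("overlapping residue ranges: nothing on one side of split")
    all_ids = dom_ids + lnk_ids
    if sorted(all_ids) != list(range(min(all_ids), max(all_ids) + 1)):
        raise ValueError("overlapping residue ranges: merged numbering not continuous")
    dom_part = domain.select_resids(dom_ids)
    lnk_part = linker.select_resids(lnk_ids)
    return Conformation(
        np.concatenate([dom_part.resids, lnk_part.resids]),
        dom_part.resnames + lnk_part.resnames,
        dom_part.names + lnk_part.names,
        dom_part.elements + lnk_part.elements,
        np.vstack([dom_part.coords, lnk_part.coords]),
        dom_part.sequence + lnk_part.sequence,
    )


def attach_second_domain(
    reference_complex: Conformation,
    partial: Conformation,
    spec: SecondDomainSpec,
):
    """Translate the second domain out of a reference complex onto the model.

    Returns (full model, accepted, diagnostics); the second domain is the
    ``second_range`` residue slice of the reference complex after
    superposition and bridge translation.
    """
    sup_ids = list(range(spec.superpose_lo, spec.superpose_hi + 1))
    names = ("N", "CA", "C", "O")
    ref_pts, par_pts = [], []
    for rid in sup_ids:
        for nm in names:
            try:
                i = reference_complex.index_of(rid, nm)
                j = partial.index_of(rid, nm)
            except KeyError:
                continue
            ref_pts.append(reference_complex.coords[i])
            par_pts.append(partial.coords[j])
    if len(ref_pts) < 3:
        raise GeometryError("superposition range shares too few backbone atoms")
    rot, trans, _ = kabsch_superpose(np.array(ref_pts), np.array(par_pts))
    ref_sup = reference_complex.transformed(rot, trans)

    try:
        i_ref = ref_sup.index_of(spec.bridge_residue, "CA")
        i_par = partial.index_of(spec.bridge_residue, "CA")
    except KeyError:
        raise GeometryError("bridge residue absent") from None
    v_bridge = partial.coords[i_par] - ref_sup.coords[i_ref]

    second = ref_sup.select_resids(
        range(spec.second_range[0], spec.second_range[1] + 1)
    ).transformed(np.eye(3), v_bridge)
    first = partial.select_resids(
        range(spec.first_range[0], spec.first_range[1] + 1)
    )
    cross = np.linalg.norm(
        first.coords[:, None, :] - second.coords[None, :, :], axis=2
    )
    n_clash = int((cross < spec.clash_distance).sum())
    accepted = bool(n_clash < spec.max_atom_clashes)
    model = Conformation(
        np.concatenate([first.resids, second.resids]),
        first.resnames + second.resnames,
        first.names + second.names,
        first.elements + second.elements,
        np.vstack([first.coords, second.coords]),
        first.sequence + second.sequence,
    )
    return model, accepted, {"n_atom_clashes": n_clash, "v_bridge": v_bridge}
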