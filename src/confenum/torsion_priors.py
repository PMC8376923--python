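"""Per-residue Ramachandran likelihood maps and torsion boxes.

A chemical-shift-based predictor emits, for each residue, a likelihood over
the 324 voxels (18x18, 20 deg x 20 deg) of the Ramachandran map.  The maps
are normalized to probability maps, voxels above a threshold are selected,
and rectangular phi x psi boxes bounding the 8-connected voxel components
(toroidal in both angles) become the sampling limits for enumeration.

Boxes may alternatively be supplied by hand in the same text format, which
reproduces manually curated choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID_SIZE",
    "VOXEL_WIDTH",
    "N_VOXELS",
    "TorsionLikelihoodMap",
    "TorsionBox",
    "EmptyLikelihoodMap",
    "NoBoxForResidue",
    "normalize_map",
    "select_voxels",
    "boxes_from_voxels",
    "voxel_centers",
    "read_likelihood_maps",
    "write_likelihood_maps",
    "read_boxes",
    "write_boxes",
]

VOXEL_WIDTH = 20.0
GRID_SIZE = int(round(360.0 / VOXEL_WIDTH))      # 18 per axis
N_VOXELS = GRID_SIZE * GRID_SIZE                 # 324


class EmptyLikelihoodMap(ValueError):
    """All-zero likelihood grid cannot be normalized."""


class NoBoxForResidue(ValueError):
    """No voxel selected for the residue; caller may copy a neighbor's boxes."""


@dataclass
class TorsionLikelihoodMap:
    """18x18 non-negative grid; voxel (a, b) covers
    phi in [-180+20a, -160+20a), psi in [-180+20b, -160+20b) degrees."""

    residue_id: int
    grid: np.ndarray = field(default_factory=lambda: np.zeros((GRID_SIZE, GRID_SIZE)))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}")
        if (self.grid < 0).any():
            raise ValueError("likelihood values must be non-negative")


@dataclass(frozen=True)
class TorsionBox:
    """Rectangular phi x psi interval attached to one residue (degrees)."""

    residue_id: int
    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float

    def __post_init__(self):
        if not (self.phi_lo < self.phi_hi and self.psi_lo < self.psi_hi):
            raise ValueError("box bounds must satisfy lo < hi")

    @property
    def phi_width(self) -> float:
        return self.phi_hi - self.phi_lo

    @property
    def psi_width(self) -> float:
        return self.psi_hi - self.psi_lo


def voxel_centers():
    """Centers of the 18 voxels along one axis: -170, -150, ..., 170."""
    return np.arange(GRID_SIZE) * VOXEL_WIDTH - 180.0 + VOXEL_WIDTH / 2.0


def normalize_map(lmap: TorsionLikelihoodMap) -> TorsionLikelihoodMap:
    """Rescale the grid so all voxel values sum to one."""
    total = lmap.grid.sum()
    if total <= 0:
        raise EmptyLikelihoodMap(f"empty likelihood map for residue {lmap.residue_id}")
    return TorsionLikelihoodMap(lmap.residue_id, lmap.grid / total)


def select_voxels(lmap: TorsionLikelihoodMap, threshold: float = 0.01):
    """Indices (a, b) of voxels whose normalized value strictly exceeds
    ``threshold``."""
    a_idx, b_idx = np.nonzero(lmap.grid > threshold)
    return {(int(a), int(b)) for a, b in zip(a_idx, b_idx)}


def _components(voxels):
    """8-connected components with toroidal wrap on both axes."""
    remaining = set(voxels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            a, b = stack.pop()
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    if da == 0 and db == 0:
                        continue
                    nb = ((a + da) % GRID_SIZE, (b + db) % GRID_SIZE)
                    if nb in remaining:
                        remaining.remove(nb)
                        comp.add(nb)
                        stack.append(nb)
        comps.append(comp)
    return comps


def _wrap_extent(indices):
    """Bounding interval of voxel indices on a periodic axis of GRID_SIZE.

    Returns (lo_index, n_cells): the component spans cells
    lo_index .. lo_index+n_cells-1 (mod GRID_SIZE).  Chooses the covering
    arc with the fewest cells (largest gap left uncovered).
    """
    idx = sorted(set(indices))
    if len(idx) == GRID_SIZE:
        return 0, GRID_SIZE
    # find the largest circular gap between consecutive occupied cells
    best_gap, best_after = -1, None
    for k, v in enumerate(idx):
        nxt = idx[(k + 1) % len(idx)]
        gap = (nxt - v - 1) % GRID_SIZE
        if gap > best_gap:
            best_gap, best_after = gap, k
    lo = idx[(best_after + 1) % len(idx)]
    n_cells = GRID_SIZE - best_gap
    return lo, n_cells


def boxes_from_voxels(voxels, residue_id: int):
    """Axis-aligned bounding boxes of the 8-connected voxel components.

    Box edges lie on the 20-degree voxel lattice; phi and psi are treated
    periodically across +-180, so a component hugging the map edge yields
    bounds that may exceed [-180, 180] on the upper side (the enumerator
    interprets torsions modulo 360).
    """
    if not voxels:
        raise NoBoxForResidue(f"no box for residue {residue_id}")
    boxes = []
    for comp in _components(voxels):
        a_lo, a_n = _wrap_extent([a for a, _ in comp])
        b_lo, b_n = _wrap_extent([b for _, b in comp])
        phi_lo = -180.0 + a_lo * VOXEL_WIDTH
        psi_lo = -180.0 + b_lo * VOXEL_WIDTH
        boxes.append(
            TorsionBox(
                residue_id,
                phi_lo, phi_lo + a_n * VOXEL_WIDTH,
                psi_lo, psi_lo + b_n * VOXEL_WIDTH,
            )
        )
    boxes.sort(key=lambda b: (b.phi_lo, b.psi_lo))
    return boxes


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def read_likelihood_maps(path):
    """Read per-voxel likelihood lines: residue_id phi_center psi_center value."""
    grids = {}
    centers = voxel_centers()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            rid = int(parts[0])
            phi_c, psi_c, val = (float(x) for x in parts[1:])
            a = int(round((phi_c + 180.0 - VOXEL_WIDTH / 2.0) / VOXEL_WIDTH))
            b = int(round((psi_c + 180.0 - VOXEL_WIDTH / 2.0) / VOXEL_WIDTH))
            if not (0 <= a < GRID_SIZE and 0 <= b < GRID_SIZE):
                raise ValueError(f"{path}:{lineno}: voxel center off-lattice")
            if abs(centers[a] - phi_c) > 1e-6 or abs(centers[b] - psi_c) > 1e-6:
                raise ValueError(f"{path}:{lineno}: voxel center off-lattice")
            grids.setdefault(rid, np.zeros((GRID_SIZE, GRID_SIZE)))[a, b] = val
    return [TorsionLikelihoodMap(rid, grid) for rid, grid in sorted(grids.items())]


def write_likelihood_maps(maps, path):
    centers = voxel_centers()
    with open(path, "w") as fh:
        fh.write("# residue_id phi_center psi_center likelihood\n")
        for lmap in maps:
            for a in range(GRID_SIZE):
                for b in range(GRID_SIZE):
                    v = lmap.grid[a, b]
                    if v != 0.0:
                        fh.write(
                            f"{lmap.residue_id} {centers[a]:.1f} {centers[b]:.1f} {v:.10g}\n"
                        )


def read_boxes(path):
    """Read box lines: residue_id phi_lo phi_hi psi_lo psi_hi."""
    boxes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            boxes.append(
                TorsionBox(int(parts[0]), *(float(x) for x in parts[1:]))
            )
    return boxes


def write_boxes(boxes, path):
    with open(path, "w") as fh:
        fh.write("# residue_id phi_lo phi_hi psi_lo psi_hi\n")
        for b in boxes:
            fh.write(
                f"{b.residue_id} {b.phi_lo:.1f} {b.phi_hi:.1f} {b.psi_lo:.1f} {b.psi_hi:.1f}\n"
            )
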