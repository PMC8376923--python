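"""Assembly of consecutive fragment conformer sets into longer chains.

Two fragments that overlap by three residues in sequence are merged by
superimposing the backbone atoms of the overlap (Kabsch), choosing the
overlap backbone atom whose two copies end up closest as the switch atom
(chain atoms come from the first fragment up to and including the switch
atom, from the second fragment after it), and rejecting any merged chain
in which two non-bonded CA atoms approach within 1 A.

An assembly step over two sets tries every pair (N_trials = |A| * |B|),
counts clash rejections, and passes the survivors through the SOM
clustering gate, reproducing the bookkeeping columns N_trials, N_clashes,
N_saved = N_trials - N_clashes and N_clust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_core import Conformation, kabsch_superpose
from .som_clustering import SOMSettings, maybe_cluster

__all__ = [
    "AssemblyCounters",
    "IncompatibleFragments",
    "assemble_pair",
    "assemble_sets",
    "assemble_chain",
    "BACKBONE_ORDER",
]

# backbone atoms used for overlap superposition, in build order
BACKBONE_ORDER = ("N", "CA", "C", "O")

CA_CLASH_CUTOFF = 1.0  # A


class IncompatibleFragments(ValueError):
    pass


@dataclass(frozen=True)
class AssemblyCounters:
    """Bookkeeping of one assembly step."""

    n_trials: int
    n_clashes: int
    n_saved: int
    n_clust: int

    def __post_init__(self):
        if self.n_saved != self.n_trials - self.n_clashes:
            raise ValueError("counter identity violated: saved != trials - clashes")
        if self.n_clust > self.n_saved:
            raise ValueError("clustered count exceeds saved count")

    @classmethod
    def from_set_sizes(cls, n_a: int, n_b: int, n_clashes: int, n_clust: int | None = None):
        """Counters implied by the all-vs-all trial rule."""
        n_trials = n_a * n_b
        n_saved = n_trials - n_clashes
        return cls(n_trials, n_clashes, n_saved, n_clust if n_clust is not None else n_saved)


def _overlap_atoms(conf: Conformation, resids, other: Conformation):
    """Indices of backbone atoms (build order) present in both copies."""
    idx = []
    for rid in resids:
        for name in BACKBONE_ORDER:
            try:
                i = conf.index_of(rid, name)
                other.index_of(rid, name)
            except KeyError:
                continue
            idx.append((rid, name, i))
    return idx


def assemble_pair(
    conf_a: Conformation,
    conf_b: Conformation,
    overlap_residues: int = 3,
    clash_cutoff: float = CA_CLASH_CUTOFF,
):
    """Merge two fragment conformations over their sequence overlap.

    Returns the merged Conformation, or None when the merged chain has a
    CA clash (non-bonded CA pair closer than ``clash_cutoff``).
    Raises IncompatibleFragments when the overlap residues disagree.
    """
    rids_a = list(conf_a.residue_ids())
    rids_b = list(conf_b.residue_ids())
    ov_a = rids_a[-overlap_residues:]
    ov_b = rids_b[:overlap_residues]
    if ov_a != ov_b:
        raise IncompatibleFragments(
            f"incompatible fragments: overlap residues {ov_a} vs {ov_b}"
        )

    def resname(conf, rid):
        i = conf.index_of(rid, "CA")
        return conf.resnames[i]

    for rid in ov_a:
        if resname(conf_a, rid) != resname(conf_b, rid):
            raise IncompatibleFragments(
                f"incompatible fragments: residue {rid} differs in sequence"
            )

    atoms = _overlap_atoms(conf_a, ov_a, conf_b)
    if len(atoms) < 3:
        raise IncompatibleFragments("overlap carries fewer than 3 shared backbone atoms")
    target = np.array([conf_a.coords[i] for _r, _n, i in atoms])
    mobile = np.array(
        [conf_b.coords[conf_b.index_of(rid, name)] for rid, name, _i in atoms]
    )
    rot, trans, _rmsd = kabsch_superpose(mobile, target)
    moved_b = conf_b.transformed(rot, trans)

    # switch atom: overlap backbone atom with the closest pair of copies
    dists = [
        np.linalg.norm(
            conf_a.coords[i] - moved_b.coords[moved_b.index_of(rid, name)]
        )
        for rid, name, i in atoms
    ]
    switch = int(np.argmin(dists))  # ties break toward the earlier atom
    sw_rid, sw_name, sw_idx_a = atoms[switch]

    # take A up to and including the switch atom, B strictly after it
    keep_a = list(range(sw_idx_a + 1))
    sw_idx_b = moved_b.index_of(sw_rid, sw_name)
    keep_b = list(range(sw_idx_b + 1, moved_b.n_atoms))
    resids = np.concatenate([conf_a.resids[keep_a], moved_b.resids[keep_b]])
    coords = np.vstack([conf_a.coords[keep_a], moved_b.coords[keep_b]])
    merged = Conformation(
        resids,
        [conf_a.resnames[i] for i in keep_a] + [moved_b.resnames[i] for i in keep_b],
        [conf_a.names[i] for i in keep_a] + [moved_b.names[i] for i in keep_b],
        [conf_a.elements[i] for i in keep_a] + [moved_b.elements[i] for i in keep_b],
        coords,
        conf_a.sequence + conf_b.sequence[overlap_residues:],
    )
    if _ca_clash(merged, clash_cutoff):
        return None
    return merged


def _ca_clash(conf: Conformation, cutoff: float) -> bool:
    """Any non-bonded CA pair (residues not adjacent in sequence) < cutoff?"""
    ca = conf.ca_coords()
    rids = conf.ca_resids()
    n = ca.shape[0]
    if n < 2:
        return False
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    for i in range(n):
        for j in range(i + 1, n):
            if abs(int(rids[i]) - int(rids[j])) <= 1:
                continue
            if dist[i, j] < cutoff:
                return True
    return False


def assemble_sets(
    set_a,
    set_b,
    overlap_residues: int = 3,
    cluster_threshold: int = 1000,
    som_settings: SOMSettings | None = None,
    seed: int = 0,
):
    """All-vs-all assembly of two conformer sets.

    Returns (clustered merged set, AssemblyCounters).
    """
    if not set_a or not set_b:
        raise ValueError("assembly requires two non-empty conformer sets")
    merged = []
    n_clashes = 0
    for a in set_a:
        for b in set_b:
            out = assemble_pair(a, b, overlap_residues)
            if out is None:
                n_clashes += 1
            else:
                merged.append(out)
    clustered = maybe_cluster(merged, cluster_threshold, som_settings, seed)
    counters = AssemblyCounters(
        n_trials=len(set_a) * len(set_b),
        n_clashes=n_clashes,
        n_saved=len(merged),
        n_clust=len(clustered),
    )
    return clustered, counters


def assemble_chain(
    fragment_sets,
    overlap_residues: int = 3,
    cluster_threshold: int = 1000,
    som_settings: SOMSettings | None = None,
    seed: int = 0,
):
    """Left-fold assembly of ordered fragment sets.

    The clustered result of step k is assembled with fragment set k+1;
    one AssemblyCounters is emitted per step.
    """
    if not fragment_sets:
        raise ValueError("no fragment sets to assemble")
    current = list(fragment_sets[0])
    counters = []
    for nxt in fragment_sets[1:]:
        current, ctr = assemble_sets(
            current, nxt, overlap_residues, cluster_threshold, som_settings, seed
        )
        counters.append(ctr)
    return current, counters
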