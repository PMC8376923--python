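"""File formats: PDB and multiframe DCD (via MDAnalysis), TSV bookkeeping.

Enumerated and assembled conformer sets are stored as one template PDB
(topology) plus a multiframe DCD (coordinates); counters and populations
go to plain TSV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry_core import AA3TO1, Conformation

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_dcd",
    "write_dcd",
    "write_counters",
    "read_counters",
    "write_populations",
]


def _universe_from_conf(conf: Conformation):
    import MDAnalysis as mda

    rids = conf.residue_ids()
    rid_to_rix = {int(r): k for k, r in enumerate(rids)}
    atom_resindex = np.array([rid_to_rix[int(r)] for r in conf.resids])
    resnames = [None] * len(rids)
    for i in range(conf.n_atoms):
        resnames[rid_to_rix[int(conf.resids[i])]] = conf.resnames[i]
    u = mda.Universe.empty(
        conf.n_atoms,
        n_residues=len(rids),
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(len(rids), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", conf.names)
    u.add_TopologyAttr("elements", conf.elements)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [int(r) for r in rids])
    u.atoms.positions = conf.coords.astype(np.float32)
    return u


def _conf_from_atomgroup(ag) -> Conformation:
    seq = "".join(AA3TO1.get(rn, "X") for rn in ag.residues.resnames)
    try:
        elements = list(ag.elements)
    except Exception:
        elements = [nm[0] for nm in ag.names]
    return Conformation(
        np.array(ag.resids),
        list(ag.resnames),
        list(ag.names),
        elements,
        ag.positions.astype(float),
        seq,
    )


def write_pdb(conf: Conformation, path) -> None:
    u = _universe_from_conf(conf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(path) -> Conformation:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _conf_from_atomgroup(u.atoms)


def write_dcd(conformations, dcd_path, template_pdb_path, template=None) -> None:
    """Write a conformer set as template PDB + multiframe DCD.

    All conformations must share the template's atom list; an empty list
    (with an explicit ``template``) yields a valid zero-frame trajectory.
    """
    from MDAnalysis.coordinates.DCD import DCDWriter

    if template is None:
        if not conformations:
            raise ValueError("cannot infer a template from an empty conformer list")
        template = conformations[0]
    write_pdb(template, template_pdb_path)
    u = _universe_from_conf(template)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with DCDWriter(str(dcd_path), n_atoms=template.n_atoms) as w:
            for conf in conformations:
                if conf.n_atoms != template.n_atoms:
                    raise ValueError("conformer atom count differs from template")
                u.atoms.positions = conf.coords.astype(np.float32)
                w.write(u.atoms)


def read_dcd(template_pdb_path, dcd_path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(template_pdb_path), str(dcd_path))
        base = _conf_from_atomgroup(u.atoms)
        out = []
        for _ts in u.trajectory:
            conf = base.copy()
            conf.coords = u.atoms.positions.astype(float)
            out.append(conf)
    return out


def write_counters(counters, path, labels=None) -> None:
    """Assembly counters as TSV (one row per step)."""
    rows = []
    for k, c in enumerate(counters):
        rows.append(
            {
                "step": labels[k] if labels else f"step{k + 1}",
                "n_trials": c.n_trials,
                "n_clashes": c.n_clashes,
                "n_saved": c.n_saved,
                "n_clust": c.n_clust,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counters(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_populations(ids, mean, sd, path) -> None:
    pd.DataFrame({"conformer": ids, "mean": mean, "sd": sd}).to_csv(
        path, sep="\t", index=False
    )
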