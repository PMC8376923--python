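"""End-to-end orchestration: boxes -> enumerate -> cluster -> assemble
[-> attach] -> fit.

The pipeline consumes per-residue likelihood maps (measured or synthetic),
extracts torsion boxes, enumerates each fragment within its boxes, reduces
each conformer set with the SOM gate, assembles fragments left to right,
optionally attaches rigid domains, and determines populations of the final
models against an observable curve.  Every stage records its counters and
the thresholds applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import io
from .assembler import assemble_chain
from .domain_attachment import AttachmentSpec, gyration_radius, search_placements
from .ensemble_fitting import (
    debye_curve,
    two_round_populations,
    weighted_scalar,
)
from .geometry_core import ForceFieldParams, default_params
from .ibp_enumerator import EnumerationSettings, FragmentSpec, run_fragment
from .som_clustering import SOMSettings, maybe_cluster
from .torsion_priors import (
    NoBoxForResidue,
    boxes_from_voxels,
    normalize_map,
    select_voxels,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; all seeds explicit."""

    sequence: str
    start_resid: int
    fragments: list                      # [(lo, hi)] resid ranges, tiling with overlap
    maps: list                           # TorsionLikelihoodMap per residue
    voxel_threshold: float = 0.01
    copy_boxes: dict = field(default_factory=dict)   # resid -> source resid
    overlap: int = 3
    enum_settings: EnumerationSettings = field(default_factory=EnumerationSettings)
    som_settings: SOMSettings = field(default_factory=lambda: SOMSettings(20, 20))
    cluster_threshold: int = 1000
    params: ForceFieldParams = field(default_factory=default_params)
    # optional domain attachment
    domain: object = None                # Conformation of the rigid domain
    attachment: AttachmentSpec | None = None
    grid_spacing: float = 2.0
    n_spin: int = 8
    # population fitting
    observable: object = None            # ObservableProfile, or None to skip
    q_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.05, 5.0, 60))
    theta: float = 10.0
    n_runs: int = 10
    keep_threshold: float = 0.01
    seed_som: int = 1
    seed_fit: int = 2

    def __post_init__(self):
        for k, (lo, hi) in enumerate(self.fragments[:-1]):
            nlo, _nhi = self.fragments[k + 1]
            if nlo != hi - self.overlap + 1:
                raise ValueError(
                    f"fragments {k} and {k + 1} do not overlap by {self.overlap}"
                )


def _boxes_per_residue(config: PipelineConfig):
    boxes = {}
    by_resid = {m.residue_id: m for m in config.maps}
    resids = range(config.start_resid, config.start_resid + len(config.sequence))
    for rid in resids:
        if rid in config.copy_boxes:
            continue
        if rid not in by_resid:
            raise NoBoxForResidue(
                f"no likelihood map for residue {rid}; add a copy_boxes directive"
            )
        lmap = normalize_map(by_resid[rid])
        voxels = select_voxels(lmap, config.voxel_threshold)
        boxes[rid] = boxes_from_voxels(voxels, rid)
    for rid, src in config.copy_boxes.items():
        boxes[rid] = [replace(b, residue_id=rid) for b in boxes[src]]
    return boxes


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every configured stage; returns the report dict."""
    report = {"stages": [], "thresholds": {
        "voxel_threshold": config.voxel_threshold,
        "save_rmsd_gate": config.enum_settings.save_rmsd_gate,
        "vdw_scale": config.enum_settings.vdw_scale,
        "cluster_threshold": config.cluster_threshold,
        "keep_threshold": config.keep_threshold,
        "theta": config.theta,
    }}

    # 1. boxes
    boxes = _boxes_per_residue(config)
    report["n_boxes"] = {rid: len(b) for rid, b in boxes.items()}
    report["stages"].append("boxes")

    # 2. enumerate + cluster per fragment
    fragment_sets = []
    enum_rows = []
    for lo, hi in config.fragments:
        offset = lo - config.start_resid
        seq = config.sequence[offset : offset + (hi - lo + 1)]
        spec = FragmentSpec(seq, lo, {r: boxes[r] for r in range(lo, hi + 1)})
        result = run_fragment(spec, config.enum_settings, config.params)
        reps = maybe_cluster(
            result.conformations,
            config.cluster_threshold,
            config.som_settings,
            config.seed_som,
        )
        fragment_sets.append(reps)
        enum_rows.append(
            {
                "range": (lo, hi),
                "n_runs": result.n_runs,
                "n_conf": result.n_saved,
                "n_clust": len(reps),
                "complete": result.complete,
            }
        )
    report["enumeration"] = enum_rows
    report["stages"].append("enumerate")

    # 3. assemble
    if len(fragment_sets) > 1:
        final_set, counters = assemble_chain(
            fragment_sets,
            config.overlap,
            config.cluster_threshold,
            config.som_settings,
            config.seed_som,
        )
        report["assembly"] = [
            {
                "n_trials": c.n_trials,
                "n_clashes": c.n_clashes,
                "n_saved": c.n_saved,
                "n_clust": c.n_clust,
            }
            for c in counters
        ]
    else:
        final_set, counters = list(fragment_sets[0]), []
        report["assembly"] = []
    report["n_final_linker"] = len(final_set)
    report["stages"].append("assemble")

    # 4. optional domain attachment
    models = final_set
    if config.domain is not None and config.attachment is not None:
        attached = []
        for linker in final_set:
            for placed, _diag in search_placements(
                config.domain, linker, config.attachment,
                config.grid_spacing, config.n_spin,
            ):
                attached.append((placed, linker))
        report["n_attached"] = len(attached)
        models = [linker for _placed, linker in attached] or final_set
        report["stages"].append("attach")

    # 5. populations against the observable
    if config.observable is not None and len(models) > 1:
        curves = [debye_curve(m, config.observable.abscissa) for m in models]
        fit = two_round_populations(
            curves,
            config.observable,
            n_runs=config.n_runs,
            keep_threshold=config.keep_threshold,
            theta=config.theta,
            seed=config.seed_fit,
        )
        rg = [gyration_radius(models[i]) for i in fit["kept"]]
        report["populations"] = {
            "kept": fit["kept"],
            "mean": fit["mean"].tolist(),
            "sd": fit["sd"].tolist(),
            "chi2": fit["chi2"],
            "entropy": fit["entropy"],
            "weighted_rg": weighted_scalar(rg, fit["mean"]),
        }
        report["stages"].append("fit")

    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if counters:
            io.write_counters(counters, out / "assembly_counters.tsv")
        if final_set:
            io.write_dcd(final_set, out / "linker.dcd", out / "linker_template.pdb")
        if "populations" in report:
            pops = report["populations"]
            io.write_populations(
                pops["kept"], pops["mean"], pops["sd"], out / "populations.tsv"
            )
    return report
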