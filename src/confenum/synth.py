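"""Synthetic fixtures: likelihood maps, peptides and known-weight ensembles.

The generator emulates the pipeline's inputs without any deposited data:
per-residue torsion preferences are mixtures of 2D Gaussians on the torus
(means in the alpha-helical and beta-strand basins by default), integrated
over the 20x20-degree voxel grid to give likelihood maps; conformers are
built directly from torsions drawn from those mixtures; observable curves
are population-weighted mixtures of per-conformer predictions with
relative Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble_fitting import ObservableProfile, debye_curve, pre_profile
from .geometry_core import ForceFieldParams, build_backbone, default_params
from .torsion_priors import (
    GRID_SIZE,
    VOXEL_WIDTH,
    TorsionLikelihoodMap,
    normalize_map,
)

__all__ = [
    "TorusGaussianMixture",
    "SyntheticScenario",
    "ALPHA_MODE",
    "BETA_MODE",
    "make_synthetic_maps",
    "sample_torsions",
    "make_conformers",
    "make_synthetic_ensemble",
    "make_recovery_ensemble",
    "RECOVERY_SEQUENCE",
    "RECOVERY_TRUE_WEIGHTS",
]

ALPHA_MODE = (-63.0, -43.0)   # deg, helical basin center
BETA_MODE = (-120.0, 130.0)   # deg, extended basin center


@dataclass
class TorusGaussianMixture:
    """Mixture of isotropic-per-axis wrapped Gaussians on the (phi, psi) torus."""

    means: list                  # [(phi, psi), ...] deg
    sigmas: list                 # [(s_phi, s_psi), ...] deg
    weights: list

    def __post_init__(self):
        if not (len(self.means) == len(self.sigmas) == len(self.weights)):
            raise ValueError("mixture component lists must align")
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("mixture weights must be a probability vector")

    def density(self, phi, psi) -> np.ndarray:
        """Wrapped-Gaussian mixture density (three wraps per axis suffice
        for sigma << 360)."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        total = np.zeros(np.broadcast(phi, psi).shape)
        for (m_phi, m_psi), (s_phi, s_psi), w in zip(
            self.means, self.sigmas, self.weights
        ):
            gp = np.zeros_like(total)
            gs = np.zeros_like(total)
            for k in (-1, 0, 1):
                gp += np.exp(-0.5 * ((phi - m_phi + 360.0 * k) / s_phi) ** 2)
                gs += np.exp(-0.5 * ((psi - m_psi + 360.0 * k) / s_psi) ** 2)
            total += w * gp * gs / (2 * math.pi * s_phi * s_psi)
        return total


def _default_modes() -> TorusGaussianMixture:
    return TorusGaussianMixture(
        means=[ALPHA_MODE, BETA_MODE],
        sigmas=[(8.0, 8.0), (10.0, 10.0)],
        weights=[0.5, 0.5],
    )


@dataclass
class SyntheticScenario:
    """Planted ground truth for one synthetic experiment."""

    sequence: str
    start_resid: int = 1
    torsion_modes: dict = field(default_factory=dict)   # resid -> mixture
    default_mode: TorusGaussianMixture = field(default_factory=_default_modes)
    ensemble_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.6, 0.3, 0.1])
    )
    noise: float = 0.01          # relative sd on observables
    seed: int = 0
    q_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.05, 5.0, 60))

    def __post_init__(self):
        self.ensemble_weights = np.asarray(self.ensemble_weights, dtype=float)
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if abs(self.ensemble_weights.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")

    def mixture_for(self, resid: int) -> TorusGaussianMixture:
        return self.torsion_modes.get(resid, self.default_mode)

    def resids(self):
        return list(range(self.start_resid, self.start_resid + len(self.sequence)))


def make_synthetic_maps(scenario: SyntheticScenario, subsamples: int = 5):
    """Per-residue likelihood maps: voxel-averaged mixture density, normalized."""
    offs = (np.arange(subsamples) + 0.5) / subsamples * VOXEL_WIDTH
    edges = np.arange(GRID_SIZE) * VOXEL_WIDTH - 180.0
    phi_pts = (edges[:, None] + offs[None, :]).ravel()      # GRID_SIZE*ss
    maps = []
    for rid in scenario.resids():
        mix = scenario.mixture_for(rid)
        pp, ss_ = np.meshgrid(phi_pts, phi_pts, indexing="ij")
        dens = mix.density(pp, ss_)
        grid = dens.reshape(GRID_SIZE, subsamples, GRID_SIZE, subsamples).mean(
            axis=(1, 3)
        )
        maps.append(normalize_map(TorsionLikelihoodMap(rid, grid)))
    return maps


def sample_torsions(scenario: SyntheticScenario, rng) -> list:
    """One (phi, psi) draw per residue from its planted mixture."""
    out = []
    for rid in scenario.resids():
        mix = scenario.mixture_for(rid)
        k = rng.choice(len(mix.weights), p=np.asarray(mix.weights))
        m_phi, m_psi = mix.means[k]
        s_phi, s_psi = mix.sigmas[k]
        phi = (m_phi + rng.normal(0, s_phi) + 180.0) % 360.0 - 180.0
        psi = (m_psi + rng.normal(0, s_psi) + 180.0) % 360.0 - 180.0
        out.append((phi, psi))
    return out


def make_conformers(
    scenario: SyntheticScenario,
    n: int,
    params: ForceFieldParams | None = None,
    rng=None,
):
    """Build n conformers from torsions drawn from the planted mixtures."""
    params = params or default_params()
    rng = rng or np.random.default_rng(scenario.seed)
    return [
        build_backbone(
            scenario.sequence,
            sample_torsions(scenario, rng),
            params,
            start_resid=scenario.start_resid,
        )
        for _ in range(n)
    ]


def make_synthetic_ensemble(
    scenario: SyntheticScenario,
    observable: str = "saxs",
    pre_probe: int | None = None,
):
    """Conformers + true weights + noisy population-weighted observable.

    The observed curve is the true-weight mixture of per-conformer
    predictions with pointwise relative Gaussian noise of sd
    ``scenario.noise``; the profile's uncertainties are set to the noise
    level actually applied.  Deterministic for a given scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    weights = scenario.ensemble_weights
    confs = make_conformers(scenario, len(weights), rng=rng)
    if observable == "saxs":
        members = [debye_curve(c, scenario.q_grid) for c in confs]
    elif observable == "pre":
        probe = pre_probe if pre_probe is not None else scenario.resids()[0]
        members = [pre_profile(c, probe) for c in confs]
    else:
        raise ValueError(f"unknown observable {observable!r}")
    stacked = np.stack([m.values for m in members])
    mix = weights @ stacked
    sigma = np.maximum(scenario.noise * np.abs(mix), 1e-12)
    noisy = mix + sigma * rng.standard_normal(mix.shape) if scenario.noise > 0 else mix
    obs = ObservableProfile(
        members[0].kind, members[0].abscissa.copy(), noisy,
        sigma if scenario.noise > 0 else None,
    )
    return confs, weights, members, obs


# ---------------------------------------------------------------------------
# population-recovery benchmark condition
# ---------------------------------------------------------------------------

# A 30-residue chain sampled from the alpha/beta mixture gives the ensemble
# members the global-shape diversity that makes a scattering curve
# informative about populations (shorter chains produce nearly collinear
# curves and an ill-conditioned inverse problem for any method).
RECOVERY_SEQUENCE = "AVLKEQWTYDSGNHRIMFACAVLKEQWTYD"
RECOVERY_TRUE_WEIGHTS = (0.35, 0.25, 0.20, 0.12, 0.08)


def make_recovery_ensemble(
    seed: int,
    n_decoys: int = 20,
    noise: float = 0.01,
    n_q: int = 60,
):
    """Planted-mixture benchmark: true + decoy curves and a noisy observation.

    Returns ``(curves, w_true, obs)``: an (n, n_q) array of per-conformer
    scattering curves in a seed-dependent random order, the true population
    vector (decoys at 0), and the noisy mixture as an ObservableProfile
    whose uncertainties are the applied noise level.
    """
    rng = np.random.default_rng(seed)
    scenario = SyntheticScenario(RECOVERY_SEQUENCE, seed=seed)
    n = len(RECOVERY_TRUE_WEIGHTS) + n_decoys
    confs = make_conformers(scenario, n, rng=rng)
    q = np.linspace(0.05, 5.0, n_q)
    curves = np.stack([debye_curve(c, q).values for c in confs])
    w_true = np.zeros(n)
    w_true[: len(RECOVERY_TRUE_WEIGHTS)] = RECOVERY_TRUE_WEIGHTS
    perm = rng.permutation(n)
    curves, w_true = curves[perm], w_true[perm]
    mix = w_true @ curves
    sigma = np.maximum(noise * np.abs(mix), 1e-12)
    y = mix + sigma * rng.standard_normal(mix.shape) if noise > 0 else mix
    obs = ObservableProfile("SAXS", q, y, sigma if noise > 0 else None)
    return curves, w_true, obs
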