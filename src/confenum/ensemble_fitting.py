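"""Ensemble scoring and maximum-entropy population determination.

Predicted per-conformer observable profiles (SAXS-like curves from a coarse
Debye sum, PRE intensity ratios, externally computed RDC tables) are
compared to measured profiles through RMS, Pearson R and Q
(= rms(calc - obs) / rms(obs)) metrics.  Conformer subsets are grown
greedily on R; populations are determined by minimizing

    chi^2 / 2 - theta * S,      S = -sum_i w_i ln(w_i / w0_i)

over the probability simplex (softmax reparameterization, gradient-based),
with the two-round protocol: ten fits from random starts, conformers whose
summed population exceeds a threshold are kept, and ten more fits on the
reduced set give the reported mean +- sd populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry_core import Conformation

__all__ = [
    "ObservableProfile",
    "FitMetrics",
    "WeightVector",
    "MaxEntResult",
    "fit_metrics",
    "ensemble_profile",
    "greedy_select",
    "maxent_reweight",
    "two_round_populations",
    "debye_curve",
    "pre_profile",
    "weighted_scalar",
    "read_profile",
    "write_profile",
]


@dataclass
class ObservableProfile:
    """One measured or predicted observable curve."""

    kind: str                     # "PRE" | "RDC" | "SAXS"
    abscissa: np.ndarray          # residue index or q (nm^-1)
    values: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.abscissa) != len(self.values):
            raise ValueError("abscissa/values length mismatch")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if len(self.uncertainties) != len(self.values):
                raise ValueError("uncertainties length mismatch")
            if (self.uncertainties <= 0).any():
                raise ValueError("uncertainties must be positive")


@dataclass(frozen=True)
class FitMetrics:
    rms: float
    r: float
    q: float


@dataclass
class WeightVector:
    weights: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        for w in (self.weights, self.reference):
            if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("populations must be non-negative and sum to 1")


@dataclass
class MaxEntResult:
    weights: WeightVector
    chi2: float
    entropy: float               # S = -sum w ln(w/w0), <= 0 away from w0


def _check_matching(calc: ObservableProfile, obs: ObservableProfile):
    if len(calc.values) != len(obs.values) or not np.allclose(
        calc.abscissa, obs.abscissa
    ):
        raise ValueError("profiles have mismatched abscissae")


def fit_metrics(calc: ObservableProfile, obs: ObservableProfile) -> FitMetrics:
    """RMS deviation, Pearson correlation and Q factor of calc vs obs."""
    _check_matching(calc, obs)
    diff = calc.values - obs.values
    rms = math.sqrt(float(np.mean(diff * diff)))
    if np.std(obs.values) == 0 or np.std(calc.values) == 0:
        raise ValueError("R undefined: zero-variance profile")
    r = float(np.corrcoef(calc.values, obs.values)[0, 1])
    rms_obs = math.sqrt(float(np.mean(obs.values ** 2)))
    q = rms / rms_obs if rms_obs > 0 else math.inf
    return FitMetrics(rms, r, q)


def ensemble_profile(members, weights) -> ObservableProfile:
    """Pointwise weighted mean of member profiles."""
    if isinstance(weights, WeightVector):
        weights = weights.weights
    weights = np.asarray(weights, dtype=float)
    if len(members) != len(weights):
        raise ValueError("weights/members length mismatch")
    base = members[0]
    for m in members[1:]:
        _check_matching(m, base)
    stacked = np.stack([m.values for m in members])
    return ObservableProfile(
        base.kind, base.abscissa.copy(), weights @ stacked, None
    )


def greedy_select(candidates, obs: ObservableProfile, max_size: int | None = None):
    """Grow a conformer subset, maximizing equal-weight ensemble R at each step.

    Returns (ordered index list, list of FitMetrics per subset size); the
    caller inspects the metric trajectory to pick the subset size.
    """
    if not candidates:
        raise ValueError("need at least one candidate profile")
    max_size = max_size or len(candidates)
    chosen: list[int] = []
    trajectory: list[FitMetrics] = []
    remaining = list(range(len(candidates)))
    while remaining and len(chosen) < max_size:
        best_idx, best_metrics = None, None
        for i in remaining:
            subset = chosen + [i]
            prof = ensemble_profile(
                [candidates[j] for j in subset],
                np.full(len(subset), 1.0 / len(subset)),
            )
            m = fit_metrics(prof, obs)
            if best_metrics is None or m.r > best_metrics.r:
                best_idx, best_metrics = i, m
        chosen.append(best_idx)
        remaining.remove(best_idx)
        trajectory.append(best_metrics)
    return chosen, trajectory


def _chi2(w, y, obs, sigma):
    resid = (w @ y - obs) / sigma
    return float(resid @ resid)


def _entropy(w, w0):
    mask = w > 1e-300
    return -float(np.sum(w[mask] * np.log(w[mask] / w0[mask])))


def maxent_reweight(
    predicted,
    obs: ObservableProfile,
    w0=None,
    theta: float = 10.0,
    w_init=None,
    maxiter: int = 2000,
) -> MaxEntResult:
    """Minimize chi^2/2 - theta*S over the simplex.

    ``predicted`` is a list of per-conformer ObservableProfile (or an
    (m, n) array of curves on obs's abscissa).  Softmax reparameterization
    keeps the weights on the simplex; the optimizer is deterministic given
    the initial point.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if isinstance(predicted[0], ObservableProfile):
        for p in predicted:
            _check_matching(p, obs)
        y = np.stack([p.values for p in predicted])
    else:
        y = np.asarray(predicted, dtype=float)
    if not np.isfinite(y).all() or not np.isfinite(obs.values).all():
        raise ValueError("non-finite profile values")
    m = y.shape[0]
    sigma = (
        obs.uncertainties if obs.uncertainties is not None else np.ones(len(obs.values))
    )
    w0 = np.full(m, 1.0 / m) if w0 is None else np.asarray(w0, dtype=float)
    if m == 1:
        w = WeightVector(np.array([1.0]), np.array([1.0]))
        return MaxEntResult(w, _chi2(w.weights, y, obs.values, sigma), 0.0)

    ys = y / sigma
    obs_s = obs.values / sigma

    def objective(x):
        xs = x - x.max()
        e = np.exp(xs)
        w = e / e.sum()
        resid = w @ ys - obs_s
        chi2 = resid @ resid
        logratio = np.log(np.maximum(w, 1e-300) / w0)
        neg_s = float(np.sum(w * logratio))
        f = 0.5 * chi2 + theta * neg_s
        # gradient through the softmax: J = diag(w) - w w^T
        g_w = ys @ resid + theta * (logratio + 1.0)
        grad = w * (g_w - float(w @ g_w))
        return f, grad

    if w_init is None:
        x0 = np.log(w0)
    else:
        w_init = np.asarray(w_init, dtype=float)
        x0 = np.log(np.maximum(w_init, 1e-12))
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )
    xs = res.x - res.x.max()
    e = np.exp(xs)
    w = e / e.sum()
    # never accept a point worse than the reference
    if objective(np.log(np.maximum(w, 1e-300)))[0] > objective(np.log(w0))[0] + 1e-12:
        w = w0.copy()
    wv = WeightVector(w, w0)
    return MaxEntResult(wv, _chi2(w, y, obs.values, sigma), _entropy(w, w0))


def two_round_populations(
    predicted,
    obs: ObservableProfile,
    n_runs: int = 10,
    keep_threshold: float = 0.01,
    theta: float = 10.0,
    seed: int = 0,
):
    """Two-round population protocol.

    Round 1: ``n_runs`` maximum-entropy fits from random simplex starts on
    all conformers; conformers whose population summed over the runs
    exceeds ``keep_threshold`` are kept.  Round 2: ``n_runs`` more fits on
    the kept set.  Returns a dict with kept indices, per-conformer mean and
    sd populations (mean renormalized to 1), and mean chi^2 / S.
    """
    if isinstance(predicted[0], ObservableProfile):
        y = np.stack([p.values for p in predicted])
    else:
        y = np.asarray(predicted, dtype=float)
    m = y.shape[0]
    rng = np.random.default_rng(seed)

    def run_round(curves):
        k = curves.shape[0]
        w0 = np.full(k, 1.0 / k)
        ws, chi2s, ents = [], [], []
        for _ in range(n_runs):
            w_init = rng.dirichlet(np.ones(k))
            res = maxent_reweight(curves, obs, w0, theta, w_init=w_init)
            ws.append(res.weights.weights)
            chi2s.append(res.chi2)
            ents.append(res.entropy)
        return np.array(ws), np.array(chi2s), np.array(ents)

    ws1, _c1, _e1 = run_round(y)
    kept = [i for i in range(m) if ws1[:, i].sum() > keep_threshold]
    if not kept:
        raise ValueError("all conformers filtered out in round 1")
    ws2, chi2s, ents = run_round(y[kept])
    mean = ws2.mean(axis=0)
    mean = mean / mean.sum()
    sd = ws2.std(axis=0)
    return {
        "kept": kept,
        "mean": mean,
        "sd": sd,
        "chi2": float(chi2s.mean()),
        "entropy": float(ents.mean()),
    }


def debye_curve(conf: Conformation, q_grid) -> ObservableProfile:
    """Coarse Debye scattering curve over CA atoms with unit form factors.

    I(q) = sum_ij sinc(q * r_ij); I(0) = n^2; rotation-invariant.  A
    deliberately simple predictor for synthetic tests, not a solvated
    scattering model.
    """
    q = np.asarray(q_grid, dtype=float)
    ca = conf.ca_coords()
    if ca.shape[0] < 2:
        raise ValueError("need >= 2 CA atoms")
    diff = ca[:, None, :] - ca[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=2)).ravel() / 10.0  # A -> nm (q in nm^-1)
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
    return ObservableProfile("SAXS", q, s.sum(axis=1), None)


PRE_CALIBRATION = 1.0e8  # A^6; intensity ratio = exp(-c / r^6)


def pre_profile(
    conf: Conformation, probe_residue: int, calibration: float = PRE_CALIBRATION
) -> ObservableProfile:
    """Per-residue PRE intensity ratio for one spin-label position.

    Ratio = exp(-c / r^6) with r the distance from the probe site (CB, or
    CA when absent) to each residue's amide N: ~0 at contact, monotone in
    r, -> 1 far from the probe.  A declared stand-in for a full
    relaxation-matrix back-calculation, used for synthetic profiles.
    """
    try:
        probe = conf.coords[conf.index_of(probe_residue, "CB")]
    except KeyError:
        probe = conf.coords[conf.index_of(probe_residue, "CA")]
    resids, ratios = [], []
    for rid in conf.residue_ids():
        try:
            n_pos = conf.coords[conf.index_of(int(rid), "N")]
        except KeyError:
            continue
        r = float(np.linalg.norm(n_pos - probe))
        ratios.append(math.exp(-calibration / max(r, 1e-3) ** 6))
        resids.append(int(rid))
    return ObservableProfile("PRE", np.array(resids, dtype=float), np.array(ratios))


def weighted_scalar(values, weights) -> float:
    """Population-weighted average of per-conformer scalars."""
    values = np.asarray(values, dtype=float)
    if isinstance(weights, WeightVector):
        weights = weights.weights
    weights = np.asarray(weights, dtype=float)
    if len(values) != len(weights):
        raise ValueError("values/weights length mismatch")
    return float(values @ weights)


# ---------------------------------------------------------------------------
# profile text I/O: 2-3 whitespace columns (abscissa, value[, sigma])
# ---------------------------------------------------------------------------

def read_profile(path, kind: str = "SAXS", q_unit: str = "nm") -> ObservableProfile:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"{path}: empty profile")
    arr = np.array([r[:2] for r in rows])
    absc = arr[:, 0]
    if kind == "SAXS" and q_unit == "angstrom":
        absc = absc * 10.0  # A^-1 -> nm^-1
    sig = None
    if all(len(r) == 3 for r in rows):
        sig = np.array([r[2] for r in rows])
    return ObservableProfile(kind, absc, arr[:, 1], sig)


def write_profile(profile: ObservableProfile, path):
    with open(path, "w") as fh:
        fh.write(f"# {profile.kind} profile: abscissa value[ sigma]\n")
        for i in range(len(profile.values)):
            line = f"{profile.abscissa[i]:.6g} {profile.values[i]:.8g}"
            if profile.uncertainties is not None:
                line += f" {profile.uncertainties[i]:.8g}"
            fh.write(line + "\n")
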