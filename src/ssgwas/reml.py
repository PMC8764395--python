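"""Variance components by Average-Information REML.

Uni- and bivariate animal models, with exact EM fall-back steps when an AI
update would leave the parameter space, Monte-Carlo standard errors of
derived parameters (heritabilities, correlations) sampled from the inverse
AI matrix, and highest-density intervals for significance calls.

The REML iterations work on the phenotypic covariance
V = sum_k theta_k B_k (B_k the per-parameter covariance structures), with

    score_k = -0.5 [ tr(P B_k) - y' P B_k P y ]
    AI_kl   =  0.5 (B_k P y)' P (B_l P y)

and P the projection V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .mme import MixedModelSpec

log = logging.getLogger(__name__)


@dataclass
class VarComp:
    params: np.ndarray
    names: list
    ai_inv: np.ndarray
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.params))

    @property
    def sigma_a2(self) -> float:
        return float(self.as_dict()["sigma_a2"])

    @property
    def sigma_e2(self) -> float:
        return float(self.as_dict()["sigma_e2"])

    def genetic_cov(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([[d["g11"], d["g12"]], [d["g12"], d["g22"]]])

    def residual_cov(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([[d["e11"], d["e12"]], [d["e12"], d["e22"]]])


def heritability(varcomp: VarComp) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_e2)."""
    sa, se = varcomp.sigma_a2, varcomp.sigma_e2
    total = sa + se
    if total <= 0:
        raise ValueError("zero total variance; heritability undefined")
    return sa / total


def _projection(V: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 (returns P and V^-1)."""
    Vinv = np.linalg.inv(V)
    VX = Vinv @ X
    XtVX = X.T @ VX
    P = Vinv - VX @ np.linalg.solve(XtVX, VX.T)
    return P, Vinv


def _ai_iterate(y, X, blocks, theta, names, lower, max_iter, tol,
                em_update=None, pd_project=None, trace=None):
    """Generic AI-REML loop over linear covariance structures."""
    n_par = len(theta)
    trace = [] if trace is None else trace
    converged = False
    AI = np.eye(n_par)
    for it in range(max_iter):
        V = sum(t * B for t, B in zip(theta, blocks))
        P, _ = _projection(V, X)
        Py = P @ y
        BPy = [B @ Py for B in blocks]
        score = np.array([
            -0.5 * (np.sum(P * B) - Py @ B_Py)
            for B, B_Py in zip(blocks, BPy)])
        PBPy = [P @ b for b in BPy]
        AI = 0.5 * np.array([[BPy[k] @ PBPy[l] for l in range(n_par)]
                             for k in range(n_par)])
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(n_par), score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-10)
        proposal = theta + step
        used_em = False
        if np.any(proposal[lower] <= 0):
            if em_update is not None:
                proposal = em_update(theta, P, Py)
                used_em = True
            else:
                # damp the AI step until admissible
                scale = 1.0
                for _ in range(30):
                    scale *= 0.5
                    proposal = theta + scale * step
                    if np.all(proposal[lower] > 0):
                        break
                used_em = True
        if pd_project is not None:
            proposal = pd_project(proposal)
        rel = np.max(np.abs(proposal - theta) / (np.abs(theta) + 1e-12))
        trace.append((it, dict(zip(names, proposal)), used_em, rel))
        theta = proposal
        if rel < tol:
            converged = True
            break
    return theta, AI, converged, it + 1, trace


def ai_reml(spec: MixedModelSpec, start: Optional[tuple] = None,
            max_iter: int = 200, tol: float = 1e-8) -> VarComp:
    """Univariate AI-REML for (sigma_a2, sigma_e2).

    Starting values default to var(y)/2 for both components; an exact EM
    step replaces any AI update that proposes a non-positive variance.
    """
    spec.validate()
    y, X = spec.y, spec.X
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError("more fixed-effect levels than records")
    K = spec.relationship()
    idx = spec.record_animal_idx
    Kobs = K[np.ix_(idx, idx)]
    q = K.shape[0]
    vy = y.var()
    theta = np.array(start if start is not None else (vy / 2.0, vy / 2.0), dtype=float)

    def em_update(theta, P, Py):
        sa, se = theta
        tr_PK = np.sum(P * Kobs)
        tr_P = np.trace(P)
        yPKPy = Py @ Kobs @ Py
        yPPy = Py @ Py
        sa_new = sa + (sa ** 2 / q) * (yPKPy - tr_PK)
        se_new = se + (se ** 2 / n) * (yPPy - tr_P)
        floor = 1e-8 * vy
        return np.array([max(sa_new, floor), max(se_new, floor)])

    theta, AI, converged, n_iter, trace = _ai_iterate(
        y, X, [Kobs, np.eye(n)], theta, ["sigma_a2", "sigma_e2"],
        lower=np.array([True, True]), max_iter=max_iter, tol=tol,
        em_update=em_update)
    if not converged:
        raise RuntimeError(
            f"AI-REML did not converge in {max_iter} iterations; trace: "
            f"{trace[-3:]}")
    return VarComp(params=theta, names=["sigma_a2", "sigma_e2"],
                   ai_inv=np.linalg.inv(AI), converged=converged,
                   n_iter=n_iter, trace=trace)


def _bend_cov(c: np.ndarray, floor: float) -> np.ndarray:
    """Project a symmetric 2x2 matrix to the nearest PD matrix (eigenclip)."""
    vals, vecs = np.linalg.eigh(c)
    if np.all(vals > floor):
        return c
    vals = np.clip(vals, floor, None)
    return vecs @ np.diag(vals) @ vecs.T


def ai_reml_bivariate(spec1: MixedModelSpec, spec2: MixedModelSpec,
                      start: Optional[np.ndarray] = None,
                      max_iter: int = 200, tol: float = 1e-6) -> VarComp:
    """Bivariate AI-REML: 2x2 genetic and residual covariance matrices.

    Traits share the relationship matrix; records may differ between
    traits. Residual covariance applies to the two records of the same
    animal. Updates leaving the PD cone are bent back by eigenvalue
    clipping (logged in the trace through the EM flag).
    """
    for s in (spec1, spec2):
        s.validate()
    K = spec1.relationship()
    i1, i2 = spec1.record_animal_idx, spec2.record_animal_idx
    n1, n2 = len(i1), len(i2)
    n = n1 + n2
    y = np.concatenate([spec1.y, spec2.y])
    X = np.zeros((n, spec1.X.shape[1] + spec2.X.shape[1]))
    X[:n1, :spec1.X.shape[1]] = spec1.X
    X[n1:, spec1.X.shape[1]:] = spec2.X

    K11 = K[np.ix_(i1, i1)]
    K22 = K[np.ix_(i2, i2)]
    K12 = K[np.ix_(i1, i2)]

    def block(up_left=None, up_right=None, low_right=None):
        B = np.zeros((n, n))
        if up_left is not None:
            B[:n1, :n1] = up_left
        if up_right is not None:
            B[:n1, n1:] = up_right
            B[n1:, :n1] = up_right.T
        if low_right is not None:
            B[n1:, n1:] = low_right
        return B

    # residual cross-block: records of the same animal in both traits
    E12 = (i1[:, None] == i2[None, :]).astype(float)
    blocks = [
        block(up_left=K11),                       # g11
        block(up_right=K12),                      # g12
        block(low_right=K22),                     # g22
        block(up_left=np.eye(n1)),                # e11
        block(up_right=E12),                      # e12
        block(low_right=np.eye(n2)),              # e22
    ]
    names = ["g11", "g12", "g22", "e11", "e12", "e22"]
    v1, v2 = spec1.y.var(), spec2.y.var()
    if start is None:
        theta = np.array([v1 / 2, 0.0, v2 / 2, v1 / 2, 0.0, v2 / 2])
    else:
        theta = np.asarray(start, dtype=float)

    floor = 1e-8 * max(v1, v2)

    def pd_project(th):
        g = _bend_cov(np.array([[th[0], th[1]], [th[1], th[2]]]), floor)
        r = _bend_cov(np.array([[th[3], th[4]], [th[4], th[5]]]), floor)
        return np.array([g[0, 0], g[0, 1], g[1, 1], r[0, 0], r[0, 1], r[1, 1]])

    lower = np.array([True, False, True, True, False, True])
    theta, AI, converged, n_iter, trace = _ai_iterate(
        y, X, blocks, theta, names, lower=lower, max_iter=max_iter, tol=tol,
        em_update=None, pd_project=pd_project)
    if not converged:
        raise RuntimeError(f"bivariate AI-REML did not converge in {max_iter} iterations")
    return VarComp(params=theta, names=names, ai_inv=np.linalg.inv(AI),
                   converged=converged, n_iter=n_iter, trace=trace)


def genetic_correlation(varcomp: VarComp) -> float:
    g = varcomp.genetic_cov()
    return float(g[0, 1] / np.sqrt(g[0, 0] * g[1, 1]))


def phenotypic_correlation(varcomp: VarComp) -> float:
    """Phenotypic (co)variances taken as genetic + residual."""
    p = varcomp.genetic_cov() + varcomp.residual_cov()
    return float(p[0, 1] / np.sqrt(p[0, 0] * p[1, 1]))


def _default_derived(names: Sequence[str]) -> dict[str, Callable]:
    if "sigma_a2" in names:
        return {"h2": lambda d: d["sigma_a2"] / (d["sigma_a2"] + d["sigma_e2"])}
    return {
        "h2_trait1": lambda d: d["g11"] / (d["g11"] + d["e11"]),
        "h2_trait2": lambda d: d["g22"] / (d["g22"] + d["e22"]),
        "r_g": lambda d: d["g12"] / np.sqrt(d["g11"] * d["g22"]),
        "r_p": lambda d: (d["g12"] + d["e12"]) / np.sqrt(
            (d["g11"] + d["e11"]) * (d["g22"] + d["e22"])),
    }


def _hpd(draws: np.ndarray, coverage: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``coverage`` of the draws."""
    x = np.sort(draws)
    n = len(x)
    k = max(1, int(np.ceil(coverage * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:-k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def mc_standard_errors(varcomp: VarComp, n_samples: int = 10_000, seed: int = 0,
                       derived: Optional[dict[str, Callable]] = None,
                       coverage: float = 0.95) -> dict:
    """Monte-Carlo SDs and HPD intervals for derived parameters.

    Parameter vectors are drawn from a multivariate normal centered at the
    REML estimates with covariance equal to the inverse AI matrix; draws
    with non-positive variances are rejected. A correlation is flagged
    significant when its HPD interval excludes zero.
    """
    rng = np.random.default_rng(seed)
    derived = derived if derived is not None else _default_derived(varcomp.names)
    var_names = [n for n in varcomp.names if not n.startswith(("g12", "e12"))]
    draws = rng.multivariate_normal(varcomp.params, varcomp.ai_inv,
                                    size=n_samples, method="svd")
    frame = {n: draws[:, i] for i, n in enumerate(varcomp.names)}
    valid = np.ones(n_samples, dtype=bool)
    for n in var_names:
        valid &= frame[n] > 0
    n_rejected = int((~valid).sum())
    if n_rejected > 0.5 * n_samples:
        raise RuntimeError(
            f"{n_rejected}/{n_samples} draws rejected: estimates too near the boundary")
    if n_rejected:
        log.info("rejected %d invalid Monte-Carlo draws", n_rejected)
    out = {}
    est = varcomp.as_dict()
    for name, fn in derived.items():
        vals = fn({k: v[valid] for k, v in frame.items()})
        vals = vals[np.isfinite(vals)]
        lo, hi = _hpd(vals, coverage)
        out[name] = {
            "estimate": float(fn(est)),
            "sd": float(vals.std()),
            "hpd_low": lo,
            "hpd_high": hi,
            "significant": bool(lo > 0 or hi < 0),
        }
    out["n_rejected"] = n_rejected
    return out
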