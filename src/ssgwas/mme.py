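"""Henderson's mixed-model equations for the animal model.

The single-trait model is  y = X b + Z a + e  with a ~ N(0, K sigma_a2)
for a relationship matrix K (pedigree A or single-step H) supplied through
its inverse, and e ~ N(0, I sigma_e2). The coefficient matrix is

    [ X'X        X'Z                    ]
    [ Z'X   Z'Z + K^-1 sigma_e2/sigma_a2 ]

Fixed factors are encoded with the first factor at full rank and every
subsequent factor dropping its first level, which makes solutions unique
without a generalized inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp


@dataclass
class MixedModelSpec:
    y: np.ndarray                  # observed records only
    X: np.ndarray                  # records x p, full rank
    record_animal_idx: np.ndarray  # row in the animal ordering per record
    n_animals: int
    kinv: sp.spmatrix              # relationship inverse over all animals
    sigma_a2: Optional[float] = None
    sigma_e2: Optional[float] = None
    genotyped_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    K: Optional[np.ndarray] = None  # dense relationship matrix, for REML
    animal_ids: Optional[np.ndarray] = None

    def validate(self) -> None:
        if len(self.y) != self.X.shape[0] or len(self.y) != len(self.record_animal_idx):
            raise ValueError("y, X and record_animal_idx must agree in length")
        if np.isnan(self.y).any():
            raise ValueError("y must contain observed records only")

    def relationship(self) -> np.ndarray:
        """Dense K, inverting kinv if it was not supplied."""
        if self.K is None:
            self.K = np.linalg.inv(self.kinv.toarray())
        return self.K


@dataclass
class MMESolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    a22_hat: np.ndarray
    C22: Optional[np.ndarray]      # PEV block of genotyped animals, sigma_e2 scale
    fixed_names: Optional[list] = None


def design_matrix(df: pd.DataFrame, factors: Sequence[str]
                  ) -> tuple[np.ndarray, list]:
    """Fixed-effect incidence: full dummies for the first factor, drop-first
    for the rest; empty levels never appear (pandas encodes observed levels).
    Linearly dependent columns, if any remain, are removed by pivoted QR."""
    blocks, names = [], []
    for i, f in enumerate(factors):
        dummies = pd.get_dummies(df[f].astype("category"), prefix=f,
                                 drop_first=(i > 0))
        if dummies.shape[1] == 0:
            warnings.warn(f"factor {f} has a single level; absorbed")
            continue
        blocks.append(dummies.values.astype(float))
        names.extend(dummies.columns.tolist())
    if not blocks:
        return np.ones((len(df), 1)), ["intercept"]
    X = np.hstack(blocks)
    # full-rank reduction
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    rank = int((np.abs(np.diag(r)) > 1e-8 * abs(r[0, 0])).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - rank} dependent fixed-effect columns")
    return X[:, keep], [names[j] for j in keep]


def make_model_spec(pheno: pd.DataFrame, trait: str, kinv: sp.spmatrix,
                    animal_ids: np.ndarray,
                    factors: Sequence[str] = ("cg", "parity_class", "birth_month"),
                    genotyped_ids: Optional[np.ndarray] = None,
                    sigma_a2: Optional[float] = None,
                    sigma_e2: Optional[float] = None,
                    K: Optional[np.ndarray] = None) -> MixedModelSpec:
    """Assemble a MixedModelSpec from a phenotype table (NaN = no record)."""
    animal_ids = np.asarray(animal_ids)
    id_to_row = {a: i for i, a in enumerate(animal_ids)}
    obs = pheno[pheno[trait].notna()].reset_index(drop=True)
    if obs.empty:
        raise ValueError(f"no records for trait {trait}")
    X, names = design_matrix(obs, factors)
    rec_idx = np.array([id_to_row[a] for a in obs["animal"].values])
    g_idx = np.array([], dtype=int)
    if genotyped_ids is not None:
        g_idx = np.array([id_to_row[a] for a in genotyped_ids])
    spec = MixedModelSpec(y=obs[trait].values.astype(float), X=X,
                          record_animal_idx=rec_idx, n_animals=len(animal_ids),
                          kinv=kinv, sigma_a2=sigma_a2, sigma_e2=sigma_e2,
                          genotyped_idx=g_idx, K=K, animal_ids=animal_ids)
    spec.fixed_names = names
    spec.validate()
    return spec


def _z_matrix(spec: MixedModelSpec) -> sp.csr_matrix:
    n = len(spec.y)
    return sp.csr_matrix((np.ones(n), (np.arange(n), spec.record_animal_idx)),
                         shape=(n, spec.n_animals))


def build_mme(spec: MixedModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense coefficient matrix and right-hand side of the MME."""
    spec.validate()
    if spec.sigma_a2 is None or spec.sigma_e2 is None:
        raise ValueError("variance components must be set before assembling the MME")
    if spec.sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    X, y = spec.X, spec.y
    Z = _z_matrix(spec)
    k = spec.sigma_e2 / spec.sigma_a2
    XtX = X.T @ X
    XtZ = (Z.T @ X).T
    ZtZ = (Z.T @ Z).toarray()
    lhs = np.block([[XtX, XtZ],
                    [XtZ.T, ZtZ + k * spec.kinv.toarray()]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return lhs, rhs


def solve_mme(spec: MixedModelSpec, want_c22: bool = True) -> MMESolution:
    """Solve the MME directly; C22 is the genotyped block of the inverse
    coefficient matrix scaled by sigma_e2, so PEV(a22_hat) = C22 and
    Var(a22_hat) = G sigma_a2 - C22."""
    lhs, rhs = build_mme(spec)
    p = spec.X.shape[1]
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular MME coefficient matrix") from exc
    b_hat, a_hat = sol[:p], sol[p:]
    C22 = None
    if want_c22 and len(spec.genotyped_idx):
        inv = np.linalg.inv(lhs)
        block = inv[np.ix_(p + spec.genotyped_idx, p + spec.genotyped_idx)]
        C22 = block * spec.sigma_e2
    a22 = a_hat[spec.genotyped_idx] if len(spec.genotyped_idx) else np.array([])
    return MMESolution(b_hat=b_hat, a_hat=a_hat, a22_hat=a22, C22=C22,
                       fixed_names=getattr(spec, "fixed_names", None))
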