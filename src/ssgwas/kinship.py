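"""Relationship matrices for single-step evaluation.

Pedigree numerator relationship matrix A (tabular method) and its sparse
inverse (Henderson's rules with inbreeding), the genomic relationship
matrix G centered by current allele frequencies, blending G with the
identity for invertibility, tuning G to the pedigree base of the genotyped
block A22, and assembly of the combined single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

restricted to the genotyped block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import MISSING, GenotypeData


@dataclass
class AMatrix:
    values: np.ndarray
    animal_ids: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


@dataclass
class GMatrix:
    values: np.ndarray
    animal_ids: np.ndarray
    p_freqs: np.ndarray
    scale: float              # 2 * sum p_i (1 - p_i)
    lam: float = 1.0
    beta: float = 0.0
    delta: float = 1.0


@dataclass
class HInverse:
    matrix: sp.csr_matrix
    animal_ids: np.ndarray
    genotyped_idx: np.ndarray


def _parent_rows(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of sire/dam per animal, -1 for unknown; validates order."""
    ids = ped["animal"].values
    id_to_row = {a: i for i, a in enumerate(ids)}
    s_rows = np.empty(len(ped), dtype=int)
    d_rows = np.empty(len(ped), dtype=int)
    for i, (s, d) in enumerate(zip(ped["sire"].values, ped["dam"].values)):
        for arr, p in ((s_rows, s), (d_rows, d)):
            if p == 0:
                arr[i] = -1
            else:
                if p not in id_to_row or id_to_row[p] >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {p} of "
                        f"{ids[i]} does not precede it")
                arr[i] = id_to_row[p]
    return s_rows, d_rows


def build_a(ped: pd.DataFrame) -> AMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    a_ij = 0.5 (a_{sire(j),i} + a_{dam(j),i}) for i < j and
    a_ii = 1 + 0.5 a_{sire(i),dam(i)}.
    """
    s_rows, d_rows = _parent_rows(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = s_rows[i], d_rows[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return AMatrix(values=A, animal_ids=ped["animal"].values.copy())


def build_a_inverse(ped: pd.DataFrame, inbreeding: Optional[np.ndarray] = None
                    ) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    d_i = 1 - 0.25 * sum over known parents of (1 + F_parent); each animal
    contributes (1/d_i) * w w' with w = (1, -0.5, -0.5) on (i, sire, dam).
    Inbreeding coefficients are taken from the tabular A unless supplied.
    """
    s_rows, d_rows = _parent_rows(ped)
    n = len(ped)
    if inbreeding is None:
        inbreeding = build_a(ped).inbreeding
    a_diag = 1.0 + np.asarray(inbreeding, dtype=float)

    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = s_rows[i], d_rows[i]
        m = 1.0
        members = [(i, 1.0)]
        if s >= 0:
            m -= 0.25 * a_diag[s]
            members.append((s, -0.5))
        if d >= 0:
            m -= 0.25 * a_diag[d]
            members.append((d, -0.5))
        inv_m = 1.0 / m
        for j, wj in members:
            for k, wk in members:
                rows.append(j)
                cols.append(k)
                vals.append(inv_m * wj * wk)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_g(geno: GenotypeData, freqs: Optional[np.ndarray] = None) -> GMatrix:
    """Raw genomic relationship matrix G0 = M M' / (2 sum p_i q_i).

    M is the genotype matrix centered by twice the allele frequencies; by
    default the frequencies observed in the current genotyped set are used.
    Monomorphic SNPs contribute nothing to the scale and raise a warning.
    """
    if (geno.calls == MISSING).any():
        raise ValueError("G requires complete genotypes (impute first)")
    d = geno.calls.astype(float)
    p = d.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if len(p) != geno.n_snps:
        raise ValueError("frequency vector length mismatch")
    pq = p * (1.0 - p)
    n_mono = int((pq <= 0).sum())
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic SNPs excluded from the G scaling")
    scale = 2.0 * pq.sum()
    if scale <= 0:
        raise ValueError("all SNPs monomorphic; G undefined")
    M = d - 2.0 * p
    G0 = (M @ M.T) / scale
    return GMatrix(values=G0, animal_ids=geno.animal_ids.copy(),
                   p_freqs=p, scale=scale)


def centered_m(geno: GenotypeData, freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """Genotypes centered by twice the allele frequencies (the M of G0)."""
    if (geno.calls == MISSING).any():
        raise ValueError("centered M requires complete genotypes")
    d = geno.calls.astype(float)
    p = d.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    return d - 2.0 * p


def blend_g(g: GMatrix, lam: float = 0.99, beta: float = 0.01) -> GMatrix:
    """G = lam * G0 + beta * I, guarding against singular G0."""
    if not 0.0 < lam + beta <= 1.5:
        warnings.warn(f"non-standard blending weights lam={lam}, beta={beta}")
    n = g.values.shape[0]
    return GMatrix(values=lam * g.values + beta * np.eye(n),
                   animal_ids=g.animal_ids, p_freqs=g.p_freqs, scale=g.scale,
                   lam=lam, beta=beta, delta=g.delta)


def tune_g_to_a22(g: GMatrix, A22: np.ndarray) -> tuple[GMatrix, float]:
    """Put G on the pedigree base of the genotyped block.

    Mean-matching adjustment: G_adj = alpha + gamma * G with alpha, gamma
    solving  mean(diag(G_adj)) = mean(diag(A22)) and
    mean(offdiag(G_adj)) = mean(offdiag(A22)). Additionally the scalar

        delta = 1 - (0.5 / n^2) * (sum(A22) - sum(G))

    is computed and stored for the back-solve scaling. For n = 1 the
    off-diagonal constraint is dropped and only the diagonal is matched.
    """
    G = g.values
    n = G.shape[0]
    if A22.shape != G.shape:
        raise ValueError("A22 and G must share the animal ordering and size")
    md_G, md_A = np.diag(G).mean(), np.diag(A22).mean()
    if n == 1:
        alpha, gamma = md_A - md_G, 1.0
    else:
        off = ~np.eye(n, dtype=bool)
        mo_G, mo_A = G[off].mean(), A22[off].mean()
        denom = md_G - mo_G
        if abs(denom) < 1e-12:
            raise ValueError("degenerate G (constant matrix): tuning system singular")
        gamma = (md_A - mo_A) / denom
        alpha = mo_A - gamma * mo_G
    delta = 1.0 - (0.5 / n ** 2) * (A22.sum() - G.sum())
    adjusted = GMatrix(values=alpha + gamma * G, animal_ids=g.animal_ids,
                       p_freqs=g.p_freqs, scale=g.scale, lam=g.lam,
                       beta=g.beta, delta=float(delta))
    return adjusted, float(delta)


def build_h_inverse(Ainv: sp.spmatrix, A22: np.ndarray, G_adj: GMatrix,
                    genotyped_idx: np.ndarray, animal_ids: np.ndarray) -> HInverse:
    """Single-step combined inverse: add (G^-1 - A22^-1) in the genotyped block.

    ``genotyped_idx`` gives the positions of the genotyped animals within
    the full pedigree ordering of ``Ainv``.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=int)
    H = sp.lil_matrix(Ainv.copy())
    if len(genotyped_idx):
        try:
            Ginv = np.linalg.inv(G_adj.values)
        except np.linalg.LinAlgError as exc:
            raise ValueError("G is singular; blend with beta > 0 before "
                             "building H^-1") from exc
        A22inv = np.linalg.inv(A22)
        corr = Ginv - A22inv
        H[np.ix_(genotyped_idx, genotyped_idx)] = (
            H[np.ix_(genotyped_idx, genotyped_idx)].toarray() + corr)
    return HInverse(matrix=H.tocsr(), animal_ids=np.asarray(animal_ids),
                    genotyped_idx=genotyped_idx)


def h_matrix(hinv: HInverse) -> np.ndarray:
    """Dense H obtained by inverting H^-1 (desk-scale convenience)."""
    return np.linalg.inv(hinv.matrix.toarray())
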