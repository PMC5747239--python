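"""Pedigree and genomic relationship matrices, their PCA, and key ancestors.

The numerator (pedigree-expected) relationship matrix A is built with the
tabular method; the realized genomic relationship matrix G follows VanRaden's
first method with observed-sample allele frequencies. Key-ancestor selection
greedily maximises the fraction of the population's additive variation
captured by the selected set, the criterion used to pick reference animals
that "cover the gene pool" of a breed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import MISSING
from .pedigree import Pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered id list."""

    values: np.ndarray
    ids: list[str]
    kind: str  # "pedigree" (A) or "genomic" (G)

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders get a_ii = 1 and a_ij = 0 among themselves; for offspring o with
    parents s, d: a_io = 0.5 (a_is + a_id) and a_oo = 1 + 0.5 a_sd. Unknown
    parents contribute nothing, so inbreeding is accumulated implicitly.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * a[s, :i]
            if d >= 0:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(a, pedigree.ids, "pedigree")


def vanraden_G(
    genotypes: np.ndarray,
    ids: Optional[Sequence[str]] = None,
) -> RelationshipMatrix:
    """Realized genomic relationship matrix, VanRaden method 1.

    G = Z Z' / (2 sum_k p_k (1 - p_k)) with Z the genotype matrix centered by
    twice the observed alt-allele frequency per site. Monomorphic sites are
    dropped; missing genotypes are not allowed.
    """
    g = np.asarray(genotypes, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D individuals × sites matrix")
    if (g == MISSING).any() or np.isnan(g).any():
        raise ValueError("vanraden_G requires complete genotypes (impute or filter first)")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic; G is undefined")
    z = g[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (z @ z.T) / denom
    G = (G + G.T) / 2.0
    if ids is None:
        ids = [str(i) for i in range(g.shape[0])]
    return RelationshipMatrix(G, list(ids), "genomic")


@dataclass
class PcaResult:
    """Per-individual coordinates on the leading components of a GRM."""

    coordinates: np.ndarray  # n × k, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # descending, length k
    degenerate: bool  # True when the retained eigenvalues are all equal


def grm_pca(G: RelationshipMatrix | np.ndarray, k: int) -> PcaResult:
    """Principal components of a (centered) genomic relationship matrix.

    Eigenvectors of the double-centered matrix, scaled by the square root of
    their eigenvalues, in descending eigenvalue order. Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    mat = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)
    n = mat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds matrix dimension {n}")
    if k == 0:
        return PcaResult(np.empty((n, 0)), np.empty(0), False)
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    centered = c @ mat @ c
    vals, vecs = np.linalg.eigh(centered)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(k):
        top = np.argmax(np.abs(vecs[:, j]))
        if vecs[top, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    degenerate = bool(k > 1 and np.allclose(vals, vals[0], rtol=1e-8, atol=1e-10))
    return PcaResult(coords, vals, degenerate)


def captured_variation(A: np.ndarray, selected: Sequence[int], ridge: float = 1e-8) -> float:
    """Mean over the population of the additive variation explained by a set.

    c(S) = mean_j a_jS (A_SS)^-1 a_Sj, the average squared pedigree-predicted
    contribution of the selected animals to every population member.
    """
    if len(selected) == 0:
        return 0.0
    idx = np.asarray(selected)
    Ass = A[np.ix_(idx, idx)] + ridge * np.eye(len(idx))
    B = A[:, idx]
    x = np.linalg.solve(Ass, B.T)
    return float(np.mean(np.einsum("jk,kj->j", B, x)))


def select_key_ancestors(
    pedigree: Pedigree,
    n: int,
    A: Optional[RelationshipMatrix] = None,
) -> list[str]:
    """Greedy key-ancestor selection by captured additive variation.

    At each step the unselected candidate whose addition maximises
    :func:`captured_variation` over the whole pedigree is chosen. Ties are
    broken toward the older generation, then id order. Returns the ids in
    selection order.
    """
    if n > len(pedigree):
        raise ValueError(f"n={n} exceeds pedigree size {len(pedigree)}")
    if A is None:
        A = additive_relationship(pedigree)
    mat = A.values
    order = sorted(
        range(len(pedigree)),
        key=lambda i: (pedigree.records[i].generation, pedigree.records[i].id),
    )
    selected: list[int] = []
    for _ in range(n):
        best, best_c = None, -np.inf
        for i in order:
            if i in selected:
                continue
            c = captured_variation(mat, selected + [i])
            if c > best_c + 1e-12:
                best, best_c = i, c
        selected.append(best)
    return [pedigree.records[i].id for i in selected]
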