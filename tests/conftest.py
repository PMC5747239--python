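"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from bovimpute.pedigree import Pedigree
from bovimpute.simulate import simulate_founder_haplotypes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_pedigree() -> Pedigree:
    """Six animals: founders A, B; full sibs C, D; half sib E via A; F inbred (C x D)."""
    return Pedigree.from_records(
        [
            ("A", "0", "0"),
            ("B", "0", "0"),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("E", "A", "0"),
            ("F", "C", "D"),
        ]
    )


@pytest.fixture
def small_panel():
    return simulate_founder_haplotypes(
        n_haplotypes=20, n_sites=200, chrom_length_bp=1_000_000, seed=11
    )


# ----------------------------------------------------------------------------------
# Independent oracles (deliberately slow/naive; never share code with the package)
# ----------------------------------------------------------------------------------


def recursive_A(pedigree: Pedigree) -> np.ndarray:
    """Additive relationships by direct recursion on parent links."""
    order = {r.id: i for i, r in enumerate(pedigree.records)}
    parents = {r.id: (r.sire, r.dam) for r in pedigree.records}
    memo: dict[tuple[str, str], float] = {}

    def a(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        if order[x] > order[y]:
            x, y = y, x
        if (x, y) in memo:
            return memo[(x, y)]
        sy, dy = parents[y]
        if x == y:
            val = 1.0 + 0.5 * a(sy, dy)
        else:
            val = 0.5 * (a(x, sy) + a(x, dy))
        memo[(x, y)] = val
        return val

    ids = pedigree.ids
    n = len(ids)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = a(ids[i], ids[j])
    return out


def enumerate_ls_posterior(
    ref_alleles: np.ndarray,
    target: np.ndarray,
    positions: np.ndarray,
    theta: float,
    rho_per_bp: float,
) -> np.ndarray:
    """Li-Stephens state posterior by exhaustive summation over all copy paths."""
    H, T = ref_alleles.shape
    switch = 1.0 - np.exp(-rho_per_bp * np.diff(positions.astype(float)))
    post = np.zeros((T, H))
    total = 0.0
    for path in itertools.product(range(H), repeat=T):
        p = 1.0 / H
        for t in range(T):
            if t > 0:
                r = switch[t - 1]
                p *= (1.0 - r) * (path[t] == path[t - 1]) + r / H
            p *= (1.0 - theta) if ref_alleles[path[t], t] == target[t] else theta
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def explicit_gls(y: np.ndarray, g: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Two-parameter GLS (intercept + dosage) with explicit V inverse."""
    X = np.column_stack([np.ones_like(y), g])
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    beta = C @ X.T @ Vi @ y
    return float(beta[1]), float(np.sqrt(C[1, 1]))
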