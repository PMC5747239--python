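"""Dosage-based mixed-model association with a genomic relationship matrix.

The model is y = mu + g_j b_j + u + e with u ~ N(0, G sigma_a^2) and
e ~ N(0, I sigma_e^2), where g_j is the alt-allele dosage of variant j and G
the realized genomic relationship matrix. Variance components are estimated
once by REML under the null model (no variant effect), and each variant is
then tested by generalized least squares with V = G sigma_a^2 + I sigma_e^2
held fixed — the EMMAX approximation. Everything is computed in the
eigenbasis of G, so the null fit is a one-dimensional REML optimisation and
each per-variant test costs one weighted regression.

Also here: the derived fat-content phenotype (fat yield as a percentage of
milk yield against a population basis), QC and imputation-quality filters,
the Bonferroni threshold, the genomic inflation factor, and QTL region
summarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING
from .relationships import RelationshipMatrix

# Population basis values for the fat-content transform (kg per lactation
# 5-day interval, as used in routine dairy evaluation).
FY_BASIS_DEFAULT = 282.18463
MY_BASIS_DEFAULT = 7080.298

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


def fat_content(
    MY: float | np.ndarray,
    FY: float | np.ndarray,
    MY_basis: float = MY_BASIS_DEFAULT,
    FY_basis: float = FY_BASIS_DEFAULT,
) -> float | np.ndarray:
    """Fat content (percentage points) from milk- and fat-yield breeding values.

    FC = 200 * ((FY_basis + 0.5 FY) / (MY_basis + 0.5 MY) - FY_basis / MY_basis).
    Zero breeding values (or values proportional to the basis) give FC = 0.
    """
    MY = np.asarray(MY, dtype=float)
    FY = np.asarray(FY, dtype=float)
    denom = MY_basis + 0.5 * MY
    if np.any(denom <= 0):
        raise ValueError("MY_basis + 0.5*MY must be positive")
    out = 200.0 * ((FY_basis + 0.5 * FY) / denom - FY_basis / MY_basis)
    return float(out) if out.ndim == 0 else out


@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma_a2: float
    sigma_e2: float
    loglik: float
    boundary: bool = False
    _eigvals: Optional[np.ndarray] = field(default=None, repr=False)
    _eigvecs: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0

    @property
    def delta(self) -> float:
        """Residual-to-additive variance ratio sigma_e^2 / sigma_a^2."""
        return self.sigma_e2 / self.sigma_a2 if self.sigma_a2 > 0 else np.inf


def _as_matrix(G: RelationshipMatrix | np.ndarray) -> np.ndarray:
    return G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)


def null_reml(y: np.ndarray, G: RelationshipMatrix | np.ndarray) -> VarianceComponents:
    """REML fit of y = mu + u + e with u ~ N(0, G sigma_a^2).

    G is eigendecomposed once and the restricted likelihood is profiled down
    to a one-dimensional search over the heritability ratio. Solutions within
    numerical reach of h2 = 0 or 1 are flagged as boundary fits.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype vector must be complete")
    mat = _as_matrix(G)
    n = y.size
    if mat.shape != (n, n):
        raise ValueError("G dimension does not match phenotype length")
    d, U = np.linalg.eigh(mat)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(h2: float) -> float:
        w = h2 * d + (1.0 - h2)
        xwx = np.sum(xt * xt / w)
        beta = np.sum(xt * yt / w) / xwx
        r = yt - xt * beta
        s = np.sum(r * r / w)
        sigma2 = s / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2.0 * np.pi * sigma2)
            + np.sum(np.log(w))
            + np.log(xwx)
            - np.log(float(n))
            + (n - 1)
        )
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite restricted likelihood")
        return -ll

    eps = 1e-6
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(eps, 1.0 - eps), method="bounded")
    # guard against local optima near the boundaries with a coarse grid
    grid = np.linspace(eps, 1.0 - eps, 21)
    g_best = grid[int(np.argmin([neg_restricted_ll(h) for h in grid]))]
    if neg_restricted_ll(g_best) < res.fun:
        res = optimize.minimize_scalar(
            neg_restricted_ll,
            bounds=(max(eps, g_best - 0.05), min(1.0 - eps, g_best + 0.05)),
            method="bounded",
        )
    h2 = float(res.x)
    boundary = h2 < 1e-4 or h2 > 1.0 - 1e-4
    if h2 < 1e-4:
        h2 = 0.0
    w = h2 * d + (1.0 - h2)
    xwx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / xwx
    s = np.sum((yt - xt * beta) ** 2 / w)
    sigma_p2 = s / (n - 1)
    return VarianceComponents(
        sigma_a2=float(h2 * sigma_p2),
        sigma_e2=float((1.0 - h2) * sigma_p2),
        loglik=float(-res.fun),
        boundary=boundary,
        _eigvals=d,
        _eigvecs=U,
    )


@dataclass
class AssociationResult:
    """Per-variant effects, tests and scan-level diagnostics."""

    table: pd.DataFrame  # effect, se, p, zero_variance (+ chrom/pos/r2 when known)
    lambda_gc: float
    threshold: Optional[float] = None

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def significant(self, threshold: Optional[float] = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no significance threshold set")
        return self.pvalues < thr


def emmax_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    G: RelationshipMatrix | np.ndarray,
    vc: VarianceComponents,
    sites: Optional[pd.DataFrame] = None,
) -> AssociationResult:
    """Per-variant GLS with the null variance components held fixed.

    Data are decorrelated through the eigenbasis of G; each dosage column is
    then an ordinary 2-parameter weighted regression with known error
    variance, giving a Wald 1-df chi-square p-value. Variants with zero
    dosage variance are reported with effect 0, p = 1 and a flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    if y.size != n:
        raise ValueError("phenotype and dosage dimensions disagree")
    if vc._eigvals is not None and vc._eigvals.size == n:
        d, U = vc._eigvals, vc._eigvecs
    else:
        d, U = np.linalg.eigh(_as_matrix(G))
        d = np.clip(d, 0.0, None)
    w = vc.sigma_a2 * d + vc.sigma_e2
    iw = 1.0 / np.sqrt(w)
    ys = (U.T @ y) * iw
    x0 = (U.T @ np.ones(n)) * iw
    Xs = (U.T @ X) * iw[:, None]

    a = float(x0 @ x0)
    b = x0 @ Xs
    c = np.einsum("ij,ij->j", Xs, Xs)
    d0 = float(x0 @ ys)
    e = ys @ Xs
    det = a * c - b * b
    zero_var = X.var(axis=0) == 0.0
    bad = zero_var | (det <= 1e-12 * np.maximum(a * c, 1e-300))
    det_safe = np.where(bad, 1.0, det)
    beta = (a * e - b * d0) / det_safe
    var_beta = a / det_safe
    chi2 = beta * beta / var_beta
    p = stats.chi2.sf(chi2, df=1)
    beta = np.where(bad, 0.0, beta)
    se = np.where(bad, np.nan, np.sqrt(var_beta))
    p = np.where(bad, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({"effect": beta, "se": se, "p": p, "zero_variance": bad})
    if sites is not None:
        table = pd.concat([sites.reset_index(drop=True), table], axis=1)
    lam = inflation_lambda(p[~bad]) if (~bad).any() else np.nan
    return AssociationResult(table=table, lambda_gc=lam)


def qc_filter(
    genotypes: np.ndarray,
    min_maf: float = 0.01,
    max_missing: float = 0.1,
) -> np.ndarray:
    """Standard per-site QC: MAF above and missing fraction below threshold.

    Keeps sites with MAF > ``min_maf`` (computed on non-missing genotypes)
    and missing fraction < ``max_missing``; both rules must hold.
    """
    g = np.asarray(genotypes, dtype=float)
    miss = g == MISSING
    frac_missing = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(np.where(miss, np.nan, g), axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    return np.flatnonzero((maf > min_maf) & (frac_missing < max_missing))


def r2_filter(r2: np.ndarray, cutoff: float = 0.3) -> np.ndarray:
    """Sites whose imputation quality strictly exceeds the cutoff."""
    kept = np.flatnonzero(np.asarray(r2, dtype=float) > cutoff)
    if kept.size == 0:
        warnings.warn(f"no sites with imputation r2 > {cutoff}; empty scan", stacklevel=2)
    return kept


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def inflation_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("inflation_lambda requires at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


@dataclass
class QtlRegion:
    chrom: str
    start: int
    end: int
    n_sites: int
    top_pos: int
    top_p: float


def summarize_qtl(
    table: pd.DataFrame,
    threshold: float,
    merge_window_bp: int = 1_000_000,
) -> list[QtlRegion]:
    """Merge significant variants into QTL regions.

    Significant sites (p < threshold) on the same chromosome are merged while
    consecutive gaps are at most ``merge_window_bp``. The top variant is the
    smallest p, ties broken toward the smaller position.
    """
    need = {"chrom", "pos", "p"}
    if not need <= set(table.columns):
        raise ValueError(f"table must carry columns {need}")
    sig = table.loc[table["p"] < threshold, ["chrom", "pos", "p"]].sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    regions: list[QtlRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        pv = grp["p"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_window_bp) + 1
        for chunk in np.split(np.arange(pos.size), breaks):
            cp, cv = pos[chunk], pv[chunk]
            top = np.lexsort((cp, cv))[0]
            regions.append(
                QtlRegion(
                    chrom=str(chrom),
                    start=int(cp.min()),
                    end=int(cp.max()),
                    n_sites=int(cp.size),
                    top_pos=int(cp[top]),
                    top_p=float(cv[top]),
                )
            )
    return regions


class MixedModelGWAS:
    """Genome scan model: phenotype, per-variant dosages and a GRM.

    Follows the fit/results pattern: construct with data, call :meth:`fit`,
    read estimates and diagnostics off the returned :class:`GWASResults`.

    Parameters
    ----------
    y
        Phenotype vector (one value per individual).
    dosages
        n × m alt-allele dosage matrix of the variants to test.
    G
        Realized genomic relationship matrix over the same individuals
        (typically from chip-density genotypes, not the tested variants).
    sites
        Optional per-variant annotation with at least chrom/pos (and r2),
        carried into the results table.
    """

    def __init__(
        self,
        y: np.ndarray | pd.Series,
        dosages: np.ndarray,
        G: RelationshipMatrix | np.ndarray,
        sites: Optional[pd.DataFrame] = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.dosages = np.asarray(dosages, dtype=float)
        self.G = G
        self.sites = sites
        if self.dosages.shape[0] != self.y.size:
            raise ValueError("dosage rows must match phenotype length")

    def fit(self, alpha: float = 0.05) -> "GWASResults":
        vc = null_reml(self.y, self.G)
        scan = emmax_scan(self.y, self.dosages, self.G, vc, self.sites)
        thr = bonferroni_threshold(alpha, self.dosages.shape[1])
        scan.threshold = thr
        scan.table["significant"] = scan.pvalues < thr
        return GWASResults(self, vc, scan)


class GWASResults:
    """Estimates, tests and diagnostics of one mixed-model genome scan."""

    def __init__(self, model: MixedModelGWAS, vc: VarianceComponents, scan: AssociationResult):
        self.model = model
        self.variance_components = vc
        self.scan = scan

    @property
    def table(self) -> pd.DataFrame:
        return self.scan.table

    @property
    def pvalues(self) -> np.ndarray:
        return self.scan.pvalues

    @property
    def lambda_gc(self) -> float:
        return self.scan.lambda_gc

    @property
    def threshold(self) -> float:
        return self.scan.threshold

    def qtl_regions(self, merge_window_bp: int = 1_000_000) -> list[QtlRegion]:
        if not {"chrom", "pos"} <= set(self.table.columns):
            raise ValueError("QTL summarization needs chrom/pos site annotation")
        return summarize_qtl(self.table, self.threshold, merge_window_bp)

    def summary(self) -> str:
        vc = self.variance_components
        n, m = self.model.dosages.shape
        n_sig = int((self.pvalues < self.threshold).sum())
        lines = [
            "Mixed-model association scan (variance components fixed from the null fit)",
            "=" * 74,
            f"individuals: {n:>10d}    variants tested: {m}",
            f"sigma_a^2:   {vc.sigma_a2:>10.4f}    sigma_e^2:       {vc.sigma_e2:.4f}",
            f"h^2:         {vc.h2:>10.4f}    REML loglik:     {vc.loglik:.3f}"
            + ("    (boundary)" if vc.boundary else ""),
            f"lambda_gc:   {self.lambda_gc:>10.4f}",
            f"threshold:   {self.threshold:>10.3e}    significant:     {n_sig}",
        ]
        top = self.table.nsmallest(min(5, len(self.table)), "p")
        cols = [c for c in ("chrom", "pos", "effect", "se", "p") if c in top.columns]
        lines += ["-" * 74, "top variants:", top[cols].to_string(index=False)]
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Manhattan plot of -log10 p by position (needs chrom/pos columns)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.table
        x = t["pos"] if "pos" in t.columns else np.arange(len(t))
        ax.scatter(x, -np.log10(t["p"]), s=4, c="0.4")
        if self.threshold:
            ax.axhline(-np.log10(self.threshold), color="red", lw=0.8)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax
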