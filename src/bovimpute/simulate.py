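"""Synthetic pedigreed populations with sequence-density haplotypes.

The generator emulates the statistical structure of a sequenced dairy-cattle
cohort: a multi-generation pedigree with few, heavily used sires; phased
founder haplotypes with a rare-variant-heavy (U-shaped) allele-frequency
spectrum and linkage disequilibrium that decays with physical distance; gene
dropping with Poisson recombination to propagate founder haplotypes; an
HD-chip subset of common, evenly spaced sites; and polygenic + QTL phenotypes
with a controlled heritability.

All operations are deterministic given their seed. No mutation occurs during
gene dropping: every allele in the population traces back to a founder
haplotype, matching the imputation setting in which reference and target
share their variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, SampleSet, VariantSite
from .pedigree import Pedigree, PedigreeRecord


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over position-ordered sites.

    ``alleles`` has two rows per individual (rows 2i and 2i+1 belong to
    individual ``samples[i]``), values in {0, 1}.
    """

    sites: list[VariantSite]
    alleles: np.ndarray
    samples: SampleSet
    chrom_length_bp: int

    def __post_init__(self):
        n, m = len(self.samples), len(self.sites)
        if self.alleles.shape != (2 * n, m):
            raise ValueError(f"alleles shape {self.alleles.shape} != {(2 * n, m)}")
        if m and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be binary")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def genotypes(self) -> np.ndarray:
        """Alt-allele counts per individual (n × m, int8)."""
        return (self.alleles[0::2] + self.alleles[1::2]).astype(np.int8)

    def allele_frequency(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def take_individuals(self, ids: Sequence[str]) -> "HaplotypePanel":
        idx = self.samples.indices_of(ids)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(self.sites, self.alleles[rows], SampleSet(ids), self.chrom_length_bp)

    def site_indices(self, sites: Sequence[VariantSite]) -> np.ndarray:
        keys = {s.key: j for j, s in enumerate(self.sites)}
        return np.array([keys[s.key] for s in sites], dtype=np.int64)


@dataclass
class PhenotypeTruth:
    """Simulated phenotypes plus the causal architecture behind them."""

    values: pd.Series
    causal_sites: list[VariantSite]
    effects: np.ndarray
    nominal_h2: float
    realized_h2: float


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    n_sires_per_gen: int,
    offspring_per_dam: int,
    seed: int,
) -> Pedigree:
    """Cattle-like pedigree: few heavily used sires, every female a dam.

    Founders split evenly into males and females. In each generation the dams
    are the previous generation's females; each dam is mated to one of
    ``n_sires_per_gen`` sires sampled from the previous generation's males and
    produces ``offspring_per_dam`` offspring of alternating sex, so the
    population size is the deterministic
    ``n_founders + sum_g n_dams_g * offspring_per_dam``.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    males, females = [], []
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        iid = f"F{i:04d}"
        records.append(PedigreeRecord(iid, None, None, 0, sex))
        (males if sex == "M" else females).append(iid)
    for g in range(1, n_generations + 1):
        if n_sires_per_gen > len(males):
            raise ValueError(
                f"n_sires_per_gen={n_sires_per_gen} exceeds available males ({len(males)}) in generation {g - 1}"
            )
        sires = [males[i] for i in rng.choice(len(males), size=n_sires_per_gen, replace=False)]
        dams = list(females)
        new_males, new_females = [], []
        k = 0
        for dam in dams:
            sire = sires[int(rng.integers(len(sires)))]
            for _ in range(offspring_per_dam):
                sex = "M" if k % 2 == 0 else "F"
                iid = f"G{g}_{k:04d}"
                records.append(PedigreeRecord(iid, sire, dam, g, sex))
                (new_males if sex == "M" else new_females).append(iid)
                k += 1
        males, females = new_males, new_females
    return Pedigree(records)


def _sample_positions(rng: np.random.Generator, n_sites: int, chrom_length_bp: int) -> np.ndarray:
    if n_sites > chrom_length_bp:
        raise ValueError("more sites than base pairs")
    pos: np.ndarray = np.unique(rng.integers(1, chrom_length_bp + 1, size=int(n_sites * 1.2) + 16))
    while pos.size < n_sites:
        extra = rng.integers(1, chrom_length_bp + 1, size=n_sites)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n_sites, replace=False))


def simulate_founder_haplotypes(
    n_haplotypes: int,
    n_sites: int,
    chrom_length_bp: int,
    beta_shape: tuple[float, float] = (0.5, 0.5),
    copy_rate: float = 0.9,
    seed: int = 0,
    chrom: str = "1",
) -> HaplotypePanel:
    """Founder haplotypes with a U-shaped frequency spectrum and decaying LD.

    Per-site target alt-allele frequencies are drawn from Beta(a, b) (a < 1
    gives the rare-variant-heavy spectrum characteristic of sequence data).
    Each haplotype carries a latent uniform variate that persists from one
    site to the next with probability ``copy_rate ** (distance / mean
    spacing)`` and refreshes otherwise; the allele at a site is the indicator
    that the latent uniform falls below the site's target frequency. This
    first-order copying process matches the target frequencies marginally and
    induces pairwise LD that decays geometrically with physical distance
    (``copy_rate = 0`` gives fully independent sites).
    """
    a, b = beta_shape
    if a <= 0 or b <= 0:
        raise ValueError(f"degenerate Beta shape {beta_shape}; both parameters must be > 0")
    if not 0 <= copy_rate < 1:
        raise ValueError("copy_rate must be in [0, 1)")
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    positions = _sample_positions(rng, n_sites, chrom_length_bp)
    freqs = rng.beta(a, b, size=n_sites)
    mean_spacing = chrom_length_bp / n_sites
    alleles = np.empty((n_haplotypes, n_sites), dtype=np.int8)
    u = rng.random(n_haplotypes)
    alleles[:, 0] = u < freqs[0]
    for s in range(1, n_sites):
        stay = copy_rate ** ((positions[s] - positions[s - 1]) / mean_spacing) if copy_rate > 0 else 0.0
        refresh = rng.random(n_haplotypes) >= stay
        u[refresh] = rng.random(int(refresh.sum()))
        alleles[:, s] = u < freqs[s]
    nucs = rng.integers(0, 4, size=(n_sites, 2))
    bases = np.array(list("ACGT"))
    sites = [
        VariantSite(
            chrom,
            int(positions[j]),
            f"snp{j}",
            bases[nucs[j, 0]],
            bases[(nucs[j, 0] + 1 + nucs[j, 1] % 3) % 4],
        )
        for j in range(n_sites)
    ]
    samples = SampleSet([f"FP{i:05d}" for i in range(n_haplotypes // 2)])
    return HaplotypePanel(sites, alleles, samples, chrom_length_bp)


def _meiosis(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: int,
    cM_per_Mb: float,
) -> np.ndarray:
    """One gamete: recombinant mosaic of the two parental haplotypes."""
    morgans = chrom_length_bp / 1e6 * cM_per_Mb / 100.0
    n_x = rng.poisson(morgans) if morgans > 0 else 0
    start = int(rng.integers(2))
    if n_x == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xpos = np.sort(rng.uniform(1, chrom_length_bp, size=n_x))
    which = (start + np.searchsorted(xpos, positions)) % 2
    return np.where(which == 0, hap_a, hap_b)


def gene_drop(
    founder_panel: HaplotypePanel,
    pedigree: Pedigree,
    cM_per_Mb: float = 1.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Propagate founder haplotypes through a pedigree with recombination.

    Pedigree founders take the founder panel's individuals in order; each
    offspring haplotype is one gamete from each parent, with a Poisson number
    of uniformly placed crossovers per meiosis (``length_Mb * cM_per_Mb / 100``
    expected). Phase is retained exactly; no mutation is introduced.
    """
    founders = pedigree.founders
    if len(founders) > founder_panel.n_individuals:
        raise ValueError(
            f"pedigree has {len(founders)} founders but the founder panel holds "
            f"{founder_panel.n_individuals} individuals"
        )
    rng = np.random.default_rng(seed)
    positions = founder_panel.positions
    n, m = len(pedigree), founder_panel.n_sites
    alleles = np.empty((2 * n, m), dtype=np.int8)
    founder_row = {iid: k for k, iid in enumerate(founders)}
    idx = {r.id: i for i, r in enumerate(pedigree.records)}
    for i, rec in enumerate(pedigree.records):
        if rec.sire is None and rec.dam is None:
            k = founder_row[rec.id]
            alleles[2 * i] = founder_panel.alleles[2 * k]
            alleles[2 * i + 1] = founder_panel.alleles[2 * k + 1]
            continue
        for slot, parent in ((0, rec.sire), (1, rec.dam)):
            if parent is None:
                # unknown parent: draw a gamete from a random founder
                k = int(rng.integers(founder_panel.n_individuals))
                ha, hb = founder_panel.alleles[2 * k], founder_panel.alleles[2 * k + 1]
            else:
                p = idx[parent]
                ha, hb = alleles[2 * p], alleles[2 * p + 1]
            alleles[2 * i + slot] = _meiosis(
                rng, ha, hb, positions, founder_panel.chrom_length_bp, cM_per_Mb
            )
    return HaplotypePanel(
        founder_panel.sites, alleles, SampleSet(pedigree.ids), founder_panel.chrom_length_bp
    )


def select_hd_subset(
    panel: HaplotypePanel,
    n_hd: int,
    min_maf: float = 0.05,
) -> list[VariantSite]:
    """Chip-like site subset: common variants, approximately even bp spacing.

    Mimics commercial array ascertainment: only sites with MAF >= ``min_maf``
    are eligible, and ``n_hd`` of them are chosen nearest to an even grid of
    target positions spanning the eligible region.
    """
    maf = panel.maf()
    eligible = np.flatnonzero(maf >= min_maf)
    if eligible.size == 0:
        raise ValueError(f"no sites with MAF >= {min_maf}")
    if n_hd > eligible.size:
        raise ValueError(f"n_hd={n_hd} exceeds {eligible.size} eligible sites")
    if n_hd == eligible.size:
        return [panel.sites[j] for j in eligible]
    pos = panel.positions[eligible].astype(float)
    targets = np.linspace(pos[0], pos[-1], n_hd)
    chosen: list[int] = []
    lo = 0
    for i, t in enumerate(targets):
        hi = eligible.size - (n_hd - i)  # leave room for the remaining picks
        j = int(np.searchsorted(pos, t))
        cands = [c for c in (j - 1, j) if lo <= c <= hi]
        if not cands:
            cands = [min(max(lo, j), hi)]
        best = min(cands, key=lambda c: abs(pos[c] - t))
        chosen.append(int(eligible[best]))
        lo = best + 1
    return [panel.sites[j] for j in chosen]


def simulate_phenotypes(
    panel: HaplotypePanel,
    n_qtl: int,
    h2: float,
    seed: int = 0,
    qtl_fraction: float = 0.5,
    qtl_min_maf: float = 0.05,
) -> PhenotypeTruth:
    """Polygenic + QTL phenotypes with realized genetic variance fraction ~ h2.

    The genetic value is the sum of a QTL part (``n_qtl`` causal sites sampled
    among sites with MAF >= ``qtl_min_maf``, explaining ``qtl_fraction`` of the
    genetic variance) and a polygenic part (small normal effects on all
    sites). Both parts are rescaled to their target sample variances, and the
    residual is drawn with variance ``1 - h2``, so the phenotypic variance is
    ~1 and the realized heritability ~``h2``. ``qtl_fraction = 1`` removes the
    polygenic term entirely.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    if n_qtl == 0:
        qtl_fraction = 0.0
    if not 0.0 <= qtl_fraction <= 1.0:
        raise ValueError("qtl_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = panel.genotypes().astype(np.float64)
    n, m = g.shape
    maf = panel.maf()
    causal_idx = np.array([], dtype=np.int64)
    effects = np.array([])
    g_qtl = np.zeros(n)
    if n_qtl > 0:
        cands = np.flatnonzero(maf >= qtl_min_maf)
        if cands.size < n_qtl:
            raise ValueError(f"only {cands.size} sites with MAF >= {qtl_min_maf} for {n_qtl} QTL")
        causal_idx = np.sort(rng.choice(cands, size=n_qtl, replace=False))
        effects = rng.normal(size=n_qtl)
        g_qtl = g[:, causal_idx] @ effects

    def _rescale(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
        v = x.var()
        if target_var == 0 or v == 0:
            return np.zeros_like(x), 0.0
        s = np.sqrt(target_var / v)
        return (x - x.mean()) * s, s

    g_qtl, s_qtl = _rescale(g_qtl, h2 * qtl_fraction)
    effects = effects * s_qtl
    g_poly = np.zeros(n)
    if h2 * (1 - qtl_fraction) > 0:
        beta = rng.normal(size=m) / np.sqrt(m)
        g_poly, _ = _rescale(g @ beta, h2 * (1 - qtl_fraction))
    genetic = g_qtl + g_poly
    residual = rng.normal(scale=np.sqrt(max(1.0 - h2, 0.0)), size=n) if h2 < 1 else np.zeros(n)
    y = genetic + residual
    tot = y.var()
    realized = float(genetic.var() / tot) if tot > 0 else 0.0
    return PhenotypeTruth(
        values=pd.Series(y, index=list(panel.samples), name="phenotype"),
        causal_sites=[panel.sites[j] for j in causal_idx],
        effects=effects,
        nominal_h2=h2,
        realized_h2=realized,
    )
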