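"""Imputation-accuracy evaluation: scenarios, masking, metrics, aggregation.

The evaluation machinery mirrors how sequence-imputation accuracy is measured
in livestock panels: validation animals are masked down to a chip site list,
re-imputed from a reference panel, and compared to their true sequence
genotypes with three statistics — genotype concordance, centered genotype
correlation and allele-dosage correlation — computed only over eligible sites
(chip sites excluded; sites monomorphic in both reference and validation
excluded). Accuracy is additionally stratified into 13 minor-allele-frequency
classes (MAF computed in the reference panel), pooling all sites of a class
into a single vector. Cross-validated scenarios average per-individual means
within each fold first and then across folds, unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, SampleSet, VariantSite
from .imputer import LiStephensImputer, call_genotypes, dosage_from_probs
from .pedigree import Pedigree
from .relationships import select_key_ancestors
from .simulate import (
    HaplotypePanel,
    gene_drop,
    select_hd_subset,
    simulate_founder_haplotypes,
    simulate_pedigree,
)

# MAF class scheme: class 0 holds monomorphic sites and is excluded from
# evaluation; class k >= 1 is the half-open interval (lower_k, upper_k].
MAF_BOUNDARIES: tuple[float, ...] = (
    0.0, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5,
)
N_MAF_CLASSES = len(MAF_BOUNDARIES)  # 13: class 0 plus 12 intervals
EXCLUDED_MAF_CLASS = 0


def maf_class(maf: float | np.ndarray) -> np.ndarray | int:
    """Classify MAF values into the 13-class scheme (class 0 = monomorphic).

    Membership is (lower, upper]: a MAF exactly on a boundary belongs to the
    class below it, e.g. 0.025 falls in (0, 0.025].
    """
    arr = np.asarray(maf, dtype=float)
    if ((arr < 0) | (arr > 0.5)).any():
        raise ValueError("MAF must lie in [0, 0.5]")
    cls = np.searchsorted(np.asarray(MAF_BOUNDARIES[1:]), arr, side="left") + 1
    cls = np.where(arr == 0.0, EXCLUDED_MAF_CLASS, cls)
    return cls if arr.ndim else int(cls)


def maf_class_label(k: int) -> str:
    if k == 0:
        return "0"
    return f"({MAF_BOUNDARIES[k - 1]:g},{MAF_BOUNDARIES[k]:g}]"


@dataclass
class ScenarioConfig:
    """One reference/validation split (one fold of a scenario)."""

    label: str
    reference_ids: list[str]
    validation_ids: list[str]
    fold: int = 0
    chrom: Optional[str] = None
    chip_sites: Optional[list[VariantSite]] = None

    def __post_init__(self):
        if set(self.reference_ids) & set(self.validation_ids):
            raise ValueError(f"{self.label}: reference and validation sets overlap")


def build_scenarios(
    panel: HaplotypePanel,
    pedigree: Optional[Pedigree],
    scheme: str,
    params: dict,
    seed: int = 0,
) -> list[ScenarioConfig]:
    """Construct reference/validation splits for the three scenario families.

    ``key_ancestors(n)``: the n most influential pedigree animals (greedy
    captured-variation) form the reference; everyone else validates.
    ``random_cv(n, folds)``: per fold a random reference of size n, the rest
    validating; folds get disjoint references when ``folds * n`` fits in the
    pool, otherwise independent draws.
    ``nested_reference(sizes, n_validation)``: one fixed random validation set
    and strictly nested references of increasing size.
    """
    pool = list(panel.samples)
    rng = np.random.default_rng(seed)
    if scheme == "key_ancestors":
        n = params["n"]
        if n > len(pool):
            raise ValueError(f"n={n} exceeds population size {len(pool)}")
        if pedigree is None:
            raise ValueError("key_ancestors scheme requires a pedigree")
        ranked = [a for a in select_key_ancestors(pedigree, len(pedigree)) if a in set(pool)]
        reference = ranked[:n]
        validation = [s for s in pool if s not in set(reference)]
        return [ScenarioConfig(f"key_ancestors_{n}", reference, validation)]
    if scheme == "random_cv":
        n, folds = params["n"], params["folds"]
        if n > len(pool):
            raise ValueError(f"n={n} exceeds population size {len(pool)}")
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        out = []
        for f in range(folds):
            if folds * n <= len(pool):
                reference = shuffled[f * n : (f + 1) * n]
            else:
                reference = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
            validation = [s for s in pool if s not in set(reference)]
            out.append(ScenarioConfig(f"random_cv_{n}", reference, validation, fold=f))
        return out
    if scheme == "nested_reference":
        sizes = list(params["sizes"])
        if sorted(sizes) != sizes:
            raise ValueError("nested_reference sizes must be non-decreasing")
        n_val = params.get("n_validation", 20)
        if max(sizes) + n_val > len(pool):
            raise ValueError("largest reference size plus validation exceeds population")
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        validation = shuffled[:n_val]
        remaining = shuffled[n_val:]
        return [
            ScenarioConfig(f"nested_{size}", remaining[:size], list(validation))
            for size in sizes
        ]
    raise ValueError(f"unknown scenario scheme {scheme!r}")


@dataclass
class MaskedValidation:
    """Validation animals reduced to chip density (reference untouched)."""

    validation_ids: list[str]
    typed_site_index: np.ndarray
    haplotypes: np.ndarray  # 2v × T, phased truth at chip sites
    genotypes: np.ndarray  # v × T


def mask_validation(
    truth: HaplotypePanel,
    scenario: ScenarioConfig,
    chip_sites: Sequence[VariantSite],
) -> MaskedValidation:
    """Hide everything but the chip sites for the validation animals."""
    if len(chip_sites) == 0:
        raise ValueError("empty chip site set")
    typed_idx = truth.site_indices(chip_sites)
    val = truth.take_individuals(scenario.validation_ids)
    return MaskedValidation(
        list(scenario.validation_ids),
        typed_idx,
        val.alleles[:, typed_idx].copy(),
        val.genotypes()[:, typed_idx].copy(),
    )


def _monomorphic(genotypes: np.ndarray) -> np.ndarray:
    p = genotypes.mean(axis=0) / 2.0
    return (p == 0.0) | (p == 1.0)


def eligible_sites(
    chip_site_index: np.ndarray,
    ref_genotypes: np.ndarray,
    val_genotypes: np.ndarray,
) -> np.ndarray:
    """Evaluation site indices: drop chip sites and jointly monomorphic sites.

    A site is excluded when it is on the chip, or when it is monomorphic in
    the reference AND monomorphic in the validation truth (even for different
    alleles).
    """
    m = ref_genotypes.shape[1]
    keep = np.ones(m, dtype=bool)
    keep[np.asarray(chip_site_index, dtype=np.int64)] = False
    keep &= ~(_monomorphic(ref_genotypes) & _monomorphic(val_genotypes))
    return np.flatnonzero(keep)


def genotype_concordance(
    truth: np.ndarray,
    imputed: np.ndarray,
    sites: np.ndarray,
) -> np.ndarray:
    """Per-individual fraction of imputed genotypes identical to the truth.

    Missing imputed genotypes count as mismatches; missing truth is not
    allowed at evaluated sites.
    """
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        raise ValueError("empty evaluation site set")
    t = truth[:, sites]
    if (t == MISSING).any():
        raise ValueError("missing truth genotypes at evaluated sites")
    i = imputed[:, sites]
    return ((t == i) & (i != MISSING)).mean(axis=1)


def centered_correlation(
    truth: np.ndarray,
    imputed: np.ndarray,
    sites: np.ndarray,
    unit: str = "per_individual",
    center_freq: Optional[np.ndarray] = None,
) -> np.ndarray | float:
    """Pearson correlation of Calus-centered genotypes (or dosages).

    Each site is centered by twice its alt-allele frequency — the truth by the
    frequency in the validation truth (or the ``center_freq`` override), the
    imputed values by their own per-site mean — removing the frequency-driven
    expected genotype from both before correlating. ``unit="per_individual"``
    yields one correlation across sites per individual (NaN where either
    vector has zero variance); ``unit="pooled"`` correlates the concatenated
    individual × site vectors.
    """
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        raise ValueError("empty evaluation site set")
    t = truth[:, sites].astype(np.float64)
    x = imputed[:, sites].astype(np.float64)
    x = np.where(x == MISSING, np.nan, x)
    if center_freq is None:
        p = t.mean(axis=0) / 2.0
    else:
        p = np.asarray(center_freq, dtype=np.float64)[sites]
    tc = t - 2.0 * p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        xc = x - np.nanmean(x, axis=0)
    if unit == "pooled":
        return _pearson(tc.ravel(), xc.ravel())
    if unit != "per_individual":
        raise ValueError("unit must be 'per_individual' or 'pooled'")
    out = np.array([_pearson(tc[i], xc[i]) for i in range(tc.shape[0])])
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance vector in correlation; returning NaN", stacklevel=2)
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def ld_r2(columns: np.ndarray, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of allele/genotype counts at two sites."""
    x = np.asarray(columns, dtype=np.float64)
    a, b = x[:, site_i], x[:, site_j]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("ld_r2 undefined for a monomorphic site")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def per_class_accuracy(
    truth: np.ndarray,
    imputed_called: np.ndarray,
    dosages: Optional[np.ndarray],
    ref_frequencies: np.ndarray,
    sites: np.ndarray,
    center_freq: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Pooled centered correlations per MAF class (class 0 excluded).

    MAF classes are assigned from the reference-panel allele frequencies; all
    sites of a class are pooled into one individual × site vector. Classes
    with no sites are absent from the table.
    """
    sites = np.asarray(sites, dtype=np.int64)
    maf = np.minimum(ref_frequencies, 1.0 - ref_frequencies)[sites]
    cls = np.asarray(maf_class(maf))
    rows = []
    for k in range(1, N_MAF_CLASSES):
        sub = sites[cls == k]
        if sub.size == 0:
            continue
        gcorr = centered_correlation(truth, imputed_called, sub, unit="pooled", center_freq=center_freq)
        dcorr = (
            centered_correlation(truth, dosages, sub, unit="pooled", center_freq=center_freq)
            if dosages is not None
            else np.nan
        )
        rows.append(
            {
                "maf_class": k,
                "label": maf_class_label(k),
                "n_sites": int(sub.size),
                "genotype_corr": gcorr,
                "dosage_corr": dcorr,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AccuracyReport:
    """Accuracy statistics for one scenario fold."""

    scenario: str
    fold: int
    per_individual: pd.DataFrame  # id, concordance, genotype_corr, dosage_corr
    per_class: pd.DataFrame
    n_eligible_sites: int

    @property
    def mean_concordance(self) -> float:
        return float(self.per_individual["concordance"].mean())

    @property
    def mean_genotype_corr(self) -> float:
        return float(self.per_individual["genotype_corr"].mean(skipna=True))

    @property
    def mean_dosage_corr(self) -> float:
        return float(self.per_individual["dosage_corr"].mean(skipna=True))

    def individual_sd(self, metric: str = "genotype_corr") -> float:
        return float(self.per_individual[metric].std(ddof=1))


@dataclass
class ScenarioSummary:
    """Fold-aggregated accuracy for one scenario (Table-style mean and range)."""

    scenario: str
    n_folds: int
    mean_concordance: float
    mean_genotype_corr: float
    mean_dosage_corr: float
    range_concordance: tuple[float, float]
    range_genotype_corr: tuple[float, float]
    range_dosage_corr: tuple[float, float]
    individual_sd_genotype_corr: float
    per_class: pd.DataFrame


def aggregate(reports: Sequence[AccuracyReport]) -> ScenarioSummary:
    """Average fold means (unweighted) and report the across-fold range.

    Per-individual means are taken within each fold first; the scenario value
    is the unweighted average of fold means, so fold size imbalance does not
    re-weight individuals.
    """
    if len(reports) == 0:
        raise ValueError("aggregate requires at least one fold")
    conc = np.array([r.mean_concordance for r in reports])
    gcor = np.array([r.mean_genotype_corr for r in reports])
    dcor = np.array([r.mean_dosage_corr for r in reports])
    sds = np.array([r.individual_sd("genotype_corr") for r in reports])
    tables = [r.per_class.assign(fold=r.fold) for r in reports if len(r.per_class)]
    if tables:
        cat = pd.concat(tables, ignore_index=True)
        per_class = (
            cat.groupby(["maf_class", "label"], as_index=False)
            .agg(
                n_sites=("n_sites", "mean"),
                genotype_corr=("genotype_corr", "mean"),
                dosage_corr=("dosage_corr", "mean"),
            )
            .sort_values("maf_class", ignore_index=True)
        )
    else:
        per_class = pd.DataFrame()
    return ScenarioSummary(
        scenario=reports[0].scenario,
        n_folds=len(reports),
        mean_concordance=float(conc.mean()),
        mean_genotype_corr=float(np.nanmean(gcor)),
        mean_dosage_corr=float(np.nanmean(dcor)),
        range_concordance=(float(conc.min()), float(conc.max())),
        range_genotype_corr=(float(np.nanmin(gcor)), float(np.nanmax(gcor))),
        range_dosage_corr=(float(np.nanmin(dcor)), float(np.nanmax(dcor))),
        individual_sd_genotype_corr=float(np.nanmean(sds)),
        per_class=per_class,
    )


def evaluate_scenario(
    truth: HaplotypePanel,
    scenario: ScenarioConfig,
    chip_sites: Sequence[VariantSite],
    theta: float = 1e-3,
    rho_per_bp: Optional[float] = None,
    call_threshold: float = 0.3,
    imputer: str = "ls",
    centering: str = "validation",
) -> AccuracyReport:
    """Mask, impute and score one scenario fold.

    ``imputer="identity"`` passes the truth straight through (an end-to-end
    sanity mode in which every metric must be exactly 1). ``centering``
    selects the allele-frequency source for metric centering ("validation",
    "reference" or "combined").
    """
    masked = mask_validation(truth, scenario, chip_sites)
    ref_panel = truth.take_individuals(scenario.reference_ids)
    val_truth = truth.take_individuals(scenario.validation_ids).genotypes()
    if imputer == "identity":
        g = val_truth
        probs = np.zeros((g.shape[0], g.shape[1], 3))
        np.put_along_axis(probs, g[..., None].astype(np.int64), 1.0, axis=-1)
        dosages = dosage_from_probs(probs)
        called = call_genotypes(probs, call_threshold)
    elif imputer == "ls":
        model = LiStephensImputer(ref_panel, theta=theta, rho_per_bp=rho_per_bp)
        result = model.impute(masked.haplotypes, masked.typed_site_index, scenario.validation_ids)
        dosages = result.dosages
        called = result.call(call_threshold)
    else:
        raise ValueError(f"unknown imputer {imputer!r}")

    ref_g = ref_panel.genotypes()
    sites = eligible_sites(masked.typed_site_index, ref_g, val_truth)
    if centering == "validation":
        cf = None
    elif centering == "reference":
        cf = ref_g.mean(axis=0) / 2.0
    elif centering == "combined":
        cf = np.concatenate([ref_g, val_truth]).mean(axis=0) / 2.0
    else:
        raise ValueError(f"unknown centering {centering!r}")

    conc = genotype_concordance(val_truth, called, sites)
    gcorr = centered_correlation(val_truth, called, sites, "per_individual", cf)
    dcorr = centered_correlation(val_truth, dosages, sites, "per_individual", cf)
    per_individual = pd.DataFrame(
        {
            "id": masked.validation_ids,
            "concordance": conc,
            "genotype_corr": gcorr,
            "dosage_corr": dcorr,
        }
    )
    per_class = per_class_accuracy(
        val_truth, called, dosages, ref_panel.allele_frequency(), sites, cf
    )
    return AccuracyReport(scenario.label, scenario.fold, per_individual, per_class, int(sites.size))


@dataclass
class BenchmarkConfig:
    """Everything one synthetic benchmark run needs, seeds included."""

    seed: int = 0
    # population: 20 founders + two generations of 40 and 80 -> 140 individuals
    n_founders: int = 20
    n_generations: int = 2
    n_sires_per_gen: int = 4
    offspring_per_dam: int = 4
    # sequence panel
    n_sites: int = 20_000
    chrom_length_bp: int = 42_000_000
    beta_shape: tuple[float, float] = (0.5, 0.5)
    copy_rate: float = 0.9
    cM_per_Mb: float = 1.0
    # chip
    n_hd: int = 400
    chip_min_maf: float = 0.05
    # scenarios
    scheme: str = "nested_reference"
    scheme_params: dict = field(default_factory=lambda: {"sizes": [20, 60, 120], "n_validation": 20})
    # imputer
    imputer: str = "ls"
    theta: float = 1e-3
    rho_per_bp: Optional[float] = None
    call_threshold: float = 0.3
    centering: str = "validation"


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    truth: HaplotypePanel
    pedigree: Pedigree
    chip_sites: list[VariantSite]
    reports: list[AccuracyReport]
    summaries: list[ScenarioSummary]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": [s.scenario for s in self.summaries],
                "n_folds": [s.n_folds for s in self.summaries],
                "concordance": [s.mean_concordance for s in self.summaries],
                "genotype_corr": [s.mean_genotype_corr for s in self.summaries],
                "dosage_corr": [s.mean_dosage_corr for s in self.summaries],
                "individual_sd": [s.individual_sd_genotype_corr for s in self.summaries],
            }
        )


def simulate_population(config: BenchmarkConfig) -> tuple[HaplotypePanel, Pedigree, list[VariantSite]]:
    """Pedigree + gene-dropped truth panel + chip manifest from one config."""
    ss = np.random.SeedSequence(config.seed)
    s_ped, s_founder, s_drop = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    pedigree = simulate_pedigree(
        config.n_founders,
        config.n_generations,
        config.n_sires_per_gen,
        config.offspring_per_dam,
        seed=s_ped,
    )
    founders = simulate_founder_haplotypes(
        n_haplotypes=2 * config.n_founders,
        n_sites=config.n_sites,
        chrom_length_bp=config.chrom_length_bp,
        beta_shape=config.beta_shape,
        copy_rate=config.copy_rate,
        seed=s_founder,
    )
    truth = gene_drop(founders, pedigree, config.cM_per_Mb, seed=s_drop)
    chip = select_hd_subset(truth, config.n_hd, config.chip_min_maf)
    return truth, pedigree, chip


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Simulate, split, mask, impute and score; fully seed-deterministic."""
    truth, pedigree, chip = simulate_population(config)
    s_scen = int(np.random.SeedSequence(config.seed).spawn(4)[3].generate_state(1)[0] % 2**31)
    scenarios = build_scenarios(truth, pedigree, config.scheme, config.scheme_params, seed=s_scen)
    reports = [
        evaluate_scenario(
            truth,
            sc,
            chip,
            theta=config.theta,
            rho_per_bp=config.rho_per_bp,
            call_threshold=config.call_threshold,
            imputer=config.imputer,
            centering=config.centering,
        )
        for sc in scenarios
    ]
    by_label: dict[str, list[AccuracyReport]] = {}
    for r in reports:
        by_label.setdefault(r.scenario, []).append(r)
    summaries = [aggregate(rs) for rs in by_label.values()]
    return BenchmarkResult(config, truth, pedigree, chip, reports, summaries)
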