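"""Readers and writers for the formats the pipeline touches.

VCF 4.2 is the carrier format for genotype panels (GT, optional DS FORMAT
fields, optional per-site R2 in INFO). Only biallelic SNP records are
accepted; multiallelic records and indels are rejected with their site
identity. Pedigrees are whitespace- or comma-delimited text with columns
``id sire dam`` ("0"/empty = unknown parent, extra columns ignored); chip
manifests are "chrom pos" site lists. Coordinates are 1-based throughout.

Missing genotypes are coded by the sentinel :data:`MISSING` (-1), never 0.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._errors import DimensionError, MultiallelicError, PedigreeError, VcfParseError
from .pedigree import Pedigree

MISSING = -1

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: 1-based position, single-nucleotide REF/ALT."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos} ref and alt alleles identical")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class SampleSet(Sequence):
    """Ordered collection of unique individual identifiers."""

    def __init__(self, ids: Sequence[str]):
        self._ids = [str(i) for i in ids]
        if len(set(self._ids)) != len(self._ids):
            raise ValueError("sample identifiers must be unique")
        self._pos = {s: i for i, s in enumerate(self._ids)}

    def __len__(self):
        return len(self._ids)

    def __getitem__(self, i):
        return self._ids[i]

    def __iter__(self):
        return iter(self._ids)

    def __contains__(self, s):
        return s in self._pos

    def __eq__(self, other):
        return isinstance(other, SampleSet) and self._ids == list(other)

    def __repr__(self):
        return f"SampleSet(n={len(self._ids)})"

    def index_of(self, sample: str) -> int:
        return self._pos[sample]

    def indices_of(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self._pos[s] for s in samples], dtype=np.int64)


def _check_site_order(sites: Sequence[VariantSite]) -> None:
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            raise VcfParseError(
                f"sites not strictly ordered by position within chromosome at {s.chrom}:{s.pos}"
            )
        last[s.chrom] = s.pos


@dataclass
class VcfData:
    """In-memory contents of one VCF panel.

    ``haplotypes`` is populated only when every genotype in the file is phased
    and non-missing (rows 2i, 2i+1 belong to individual i); ``genotypes`` is
    always populated (alt-allele counts, :data:`MISSING` for "./.").
    """

    sites: list[VariantSite]
    samples: SampleSet
    genotypes: np.ndarray
    haplotypes: Optional[np.ndarray] = None
    dosages: Optional[np.ndarray] = None
    info_r2: Optional[np.ndarray] = None

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None


def _scan_for_malformed_line(path: str | Path) -> Optional[tuple[int, str]]:
    """Best-effort localisation of a structurally broken data line."""
    n_cols = None
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if n_cols is None:
                n_cols = len(fields)
            if len(fields) < 8 or len(fields) != n_cols:
                return lineno, line[:80]
            if not fields[1].isdigit():
                return lineno, line[:80]
    return None


def read_vcf(path: str | Path) -> VcfData:
    """Read a biallelic-SNP VCF with GT and optional DS fields.

    Phased records ("0|1") contribute haplotype alleles; any unphased or
    missing genotype anywhere in the file demotes the whole panel to
    genotype-only. Record order is preserved and must be position-sorted
    within each chromosome.
    """
    path = str(path)
    located = _scan_for_malformed_line(path)  # htslib tolerates junk; we do not
    if located is not None:
        raise VcfParseError(f"malformed VCF line {located[0]}: {located[1]!r}")
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = SampleSet(vcf.samples)
    n = len(samples)
    sites: list[VariantSite] = []
    gts: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    ds: list[np.ndarray] = []
    r2: list[float] = []
    all_phased = True
    any_ds = False
    any_r2 = False
    try:
        for v in vcf:
            if len(v.ALT) != 1:
                raise MultiallelicError(
                    f"multiallelic record at {v.CHROM}:{v.POS} (ALT={','.join(v.ALT)})"
                )
            if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                raise VcfParseError(f"non-SNP record at {v.CHROM}:{v.POS}")
            sites.append(
                VariantSite(str(v.CHROM), int(v.POS), v.ID or ".", v.REF, v.ALT[0])
            )
            galleles = np.asarray(v.genotypes, dtype=np.int64).reshape(n, 3) if n else np.empty((0, 3), np.int64)
            a0, a1, phased = galleles[:, 0], galleles[:, 1], galleles[:, 2]
            miss = (a0 < 0) | (a1 < 0)
            g = np.where(miss, MISSING, a0 + a1).astype(np.int8)
            gts.append(g)
            if all_phased and (miss.any() or (n > 0 and not phased.all())):
                all_phased = False
            if all_phased:
                h = np.empty(2 * n, dtype=np.int8)
                h[0::2] = a0
                h[1::2] = a1
                haps.append(h)
            try:
                d = v.format("DS")
            except KeyError:
                d = None
            if d is not None:
                any_ds = True
                ds.append(np.asarray(d, dtype=np.float64).reshape(n))
            else:
                ds.append(np.full(n, np.nan))
            site_r2 = v.INFO.get("R2")
            if site_r2 is not None:
                any_r2 = True
                r2.append(float(site_r2))
            else:
                r2.append(np.nan)
    except (MultiallelicError, VcfParseError):
        raise
    except Exception as exc:
        located = _scan_for_malformed_line(path)
        if located is not None:
            raise VcfParseError(f"malformed VCF line {located[0]}: {located[1]!r}") from exc
        raise VcfParseError(f"error parsing VCF {path}: {exc}") from exc

    _check_site_order(sites)
    m = len(sites)
    genotypes = (
        np.stack(gts, axis=1) if m and n else np.empty((n, m), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and n > 0:
        haplotypes = (
            np.stack(haps, axis=1) if m else np.empty((2 * n, 0), dtype=np.int8)
        )
    dosages = np.stack(ds, axis=1) if (any_ds and m and n) else None
    info_r2 = np.asarray(r2) if any_r2 else None
    return VcfData(sites, samples, genotypes, haplotypes, dosages, info_r2)


def write_vcf(
    sites: Sequence[VariantSite],
    samples: SampleSet | Sequence[str],
    path: str | Path,
    genotypes: Optional[np.ndarray] = None,
    haplotypes: Optional[np.ndarray] = None,
    dosages: Optional[np.ndarray] = None,
    info_r2: Optional[np.ndarray] = None,
    source: str = "bovimpute",
    seed: Optional[int] = None,
) -> None:
    """Write a VCF 4.2 with GT (phased "|" when haplotypes given) and DS to 3 decimals."""
    if not isinstance(samples, SampleSet):
        samples = SampleSet(samples)
    n, m = len(samples), len(sites)
    if genotypes is None and haplotypes is None and n > 0:
        raise DimensionError("either genotypes or haplotypes must be given")
    if haplotypes is not None and haplotypes.shape != (2 * n, m):
        raise DimensionError(f"haplotypes shape {haplotypes.shape} != {(2 * n, m)}")
    if genotypes is not None and genotypes.shape != (n, m):
        raise DimensionError(f"genotypes shape {genotypes.shape} != {(n, m)}")
    if dosages is not None and dosages.shape != (n, m):
        raise DimensionError(f"dosages shape {dosages.shape} != {(n, m)}")
    if info_r2 is not None and len(info_r2) != m:
        raise DimensionError("info_r2 length != number of sites")
    _check_site_order(sites)

    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source={source}\n")
    if seed is not None:
        buf.write(f"##bovimpute_seed={seed}\n")
    for chrom in dict.fromkeys(s.chrom for s in sites):
        buf.write(f"##contig=<ID={chrom}>\n")
    if info_r2 is not None:
        buf.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality (dosage variance ratio)">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    if dosages is not None:
        buf.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    buf.write("\t".join(header[:8] if n == 0 else header + list(samples)) + "\n")

    fmt = "GT:DS" if dosages is not None else "GT"
    for j, s in enumerate(sites):
        info = f"R2={info_r2[j]:.4f}" if info_r2 is not None else "."
        row = [s.chrom, str(s.pos), s.id, s.ref_allele, s.alt_allele, ".", "PASS", info]
        if n > 0:
            row.append(fmt)
            for i in range(n):
                if haplotypes is not None:
                    gt = f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                else:
                    g = genotypes[i, j]
                    gt = "./." if g == MISSING else ("0/0", "0/1", "1/1")[g]
                row.append(f"{gt}:{dosages[i, j]:.3f}" if dosages is not None else gt)
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_pedigree(path: str | Path) -> Pedigree:
    """Read an ``id sire dam`` text table (whitespace or comma delimited).

    A header row is recognised when the first field is "id" (any case).
    Extra columns are ignored; "0" or empty fields mark unknown parents.
    """
    rows = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace(",", " ").split() if f]
            if len(fields) < 3:
                raise PedigreeError(f"pedigree line has <3 columns: {line!r}")
            rows.append(tuple(fields[:3]))
    if rows and rows[0][0].lower() == "id":
        rows = rows[1:]
    return Pedigree.from_records(rows)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("id sire dam generation\n")
        for r in pedigree:
            fh.write(f"{r.id} {r.sire or 0} {r.dam or 0} {r.generation}\n")


def read_site_list(path: str | Path) -> list[tuple[str, int]]:
    """Read a chip manifest: one "chrom pos" per line."""
    out = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split()[:2]
            out.append((chrom, int(pos)))
    return out


def write_site_list(sites: Sequence[VariantSite], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for s in sites:
            fh.write(f"{s.chrom} {s.pos}\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (TSV/whitespace) indexed by individual id."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def write_matrix(matrix: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
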