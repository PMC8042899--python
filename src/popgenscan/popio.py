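"""Genotype containers, VCF/population-map/GFF I/O, allele frequencies,
outgroup polarization and sliding windows.

This module is the substrate shared by every statistic in the package: a
:class:`VariantTable` holds a biallelic-SNP genotype matrix (alt-allele
counts, ``-1`` = missing) with 1-based positions; a :class:`PopulationMap`
assigns samples to populations and tags the outgroup; windows are 1-based
inclusive intervals anchored at position 1 of each chromosome.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "PopulationMap",
    "Polarization",
    "read_vcf",
    "write_vcf",
    "apply_snp_filters",
    "allele_freqs",
    "polarize",
    "derived_freqs",
    "make_windows",
    "read_gff_genes",
    "windows_to_bed",
]


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantTable:
    """Biallelic SNP matrix for one or more chromosomes.

    Attributes
    ----------
    chrom : array of str, one label per site
    pos : int64 array, 1-based, strictly increasing within each chromosome
    ref, alt : single-base allele arrays
    genotypes : int8 matrix (n_sites, n_samples); values 0/1/2 count alt
        alleles, ``MISSING`` (-1) marks a missing diploid call
    samples : ordered sample identifiers
    contig_lengths : chromosome lengths from the VCF header when present
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.samples):
            raise ValueError("genotype columns must match sample_ids")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype values must be in {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))

    def chrom_length(self, chrom: str) -> int:
        """Header contig length when present, else max observed position."""
        if chrom in self.contig_lengths:
            return int(self.contig_lengths[chrom])
        mask = self.chrom == chrom
        if not mask.any():
            raise KeyError(chrom)
        return int(self.pos[mask].max())

    def take_sites(self, index: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.genotypes[index], list(self.samples),
            dict(self.contig_lengths),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not in table") from None


@dataclass
class PopulationMap:
    """sample -> population assignment with optional outgroup role tags."""

    assignments: dict[str, str]
    outgroups: set[str] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        """Two-column TSV (sample, population); optional third column with
        the literal role ``outgroup``."""
        assignments: dict[str, str] = {}
        outgroups: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"bad popmap line: {line!r}")
                sample, pop = parts[0], parts[1]
                if sample in assignments:
                    raise ValueError(f"sample {sample} assigned twice")
                assignments[sample] = pop
                if len(parts) > 2 and parts[2].strip() == "outgroup":
                    outgroups.add(pop)
        return cls(assignments, outgroups)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                role = "\toutgroup" if pop in self.outgroups else ""
                fh.write(f"{sample}\t{pop}{role}\n")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_for(self, population: str) -> list[str]:
        names = [s for s, p in self.assignments.items() if p == population]
        if not names:
            raise KeyError(f"unknown population {population!r}")
        return names


def read_vcf(path, region_filter=None) -> VariantTable:
    """Read biallelic SNP records from a VCF into a :class:`VariantTable`.

    Multi-allelic and indel records are dropped. Genotypes are encoded as
    alt-allele counts; any missing allele makes the diploid call missing.
    ``region_filter`` restricts to ``(chrom, start, end)`` 1-based inclusive.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contig_lengths: dict[str, int] = {}
    try:
        for name, length in zip(vcf.seqnames, vcf.seqlens):
            if length:
                contig_lengths[name] = int(length)
    except AttributeError:  # header has contigs without lengths, or none
        pass

    chroms, poss, refs, alts, gts = [], [], [], [], []
    bases = {"A", "C", "G", "T"}
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        if rec.REF not in bases or rec.ALT[0] not in bases:
            continue
        if region_filter is not None:
            c, s, e = region_filter
            if rec.CHROM != c or not (s <= rec.POS <= e):
                continue
        # gts012: 0/1/2 alt count, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append(g)
    vcf.close()

    if not poss:
        warnings.warn("no biallelic SNP records found; table is empty")
        gt = np.empty((0, len(samples)), dtype=np.int8)
        return VariantTable(
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.array([], dtype=object), np.array([], dtype=object),
            gt, samples, contig_lengths,
        )
    return VariantTable(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        np.vstack(gts), samples, contig_lengths,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path) -> None:
    """Write a minimal GT-only VCF 4.2 file (deterministic byte output)."""
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write('##source=popgenscan\n')
    for name in vt.chromosomes():
        length = vt.contig_lengths.get(name)
        if length:
            out.write(f"##contig=<ID={name},length={length}>\n")
        else:
            out.write(f"##contig=<ID={name}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    out.write("\t".join(vt.samples) + "\n")
    for i in range(vt.n_sites):
        gt = "\t".join(_GT_STR[int(g)] for g in vt.genotypes[i])
        out.write(
            f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
            f"\t.\tPASS\t.\tGT\t{gt}\n"
        )
    with open(path, "w") as fh:
        fh.write(out.getvalue())


def apply_snp_filters(vt: VariantTable, max_missing_rate: float = 0.05,
                      min_maf: float = 0.05) -> VariantTable:
    """Drop sites with too much missingness or too low minor-allele frequency.

    Missing fraction and MAF are computed over non-missing diploid calls,
    mirroring PLINK's ``-geno``/``-maf`` site filters.
    """
    if not (0 <= max_missing_rate <= 1 and 0 <= min_maf <= 0.5):
        raise ValueError("filter thresholds out of range")
    g = vt.genotypes
    missing = g == MISSING
    miss_rate = missing.mean(axis=1)
    n_called = (~missing).sum(axis=1)
    alt_count = np.where(missing, 0, g).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_count / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_rate <= max_missing_rate) & (n_called > 0) & (maf >= min_maf)
    return vt.take_sites(np.flatnonzero(keep))


@dataclass
class FreqVector:
    """Per-site alt/derived allele frequency for one population.

    ``p`` is NaN wherever ``n`` (non-missing haplotype count) is zero.
    """

    p: np.ndarray
    n: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n > 0


def _pop_counts(vt: VariantTable, pm: PopulationMap, population: str):
    idx = vt.sample_indices(pm.samples_for(population))
    g = vt.genotypes[:, idx]
    missing = g == MISSING
    n = 2 * (~missing).sum(axis=1)
    alt = np.where(missing, 0, g).sum(axis=1)
    return alt.astype(np.int64), n.astype(np.int64)


def allele_freqs(vt: VariantTable, pm: PopulationMap,
                 population: str) -> FreqVector:
    """Alt-allele frequency and haplotype count per site for one population."""
    alt, n = _pop_counts(vt, pm, population)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return FreqVector(p=p, n=n)


@dataclass
class Polarization:
    """Per-site outgroup polarization.

    ``usable`` marks sites where the outgroup is fixed among non-missing
    calls; ``derived_is_alt`` says whether the alt allele is the derived one
    (the outgroup carries the ancestral allele by assumption).
    """

    usable: np.ndarray
    derived_is_alt: np.ndarray
    outgroup: str


def polarize(vt: VariantTable, pm: PopulationMap, outgroup: str) -> Polarization:
    """Assign ancestral/derived states using a fixed outgroup.

    Sites where the outgroup is polymorphic or entirely missing are flagged
    unusable and excluded from polarized statistics (no failure). Applying
    the function twice yields identical flags (it only reads the table).
    """
    alt, n = _pop_counts(vt, pm, outgroup)
    fixed_ref = (n > 0) & (alt == 0)
    fixed_alt = (n > 0) & (alt == n)
    usable = fixed_ref | fixed_alt
    return Polarization(usable=usable, derived_is_alt=fixed_ref, outgroup=outgroup)


def derived_freqs(vt: VariantTable, pm: PopulationMap, population: str,
                  pol: Polarization) -> FreqVector:
    """Derived-allele frequency per site under an outgroup polarization.

    Frequencies at unusable sites are NaN.
    """
    fv = allele_freqs(vt, pm, population)
    p = np.where(pol.derived_is_alt, fv.p, 1.0 - fv.p)
    p = np.where(pol.usable, p, np.nan)
    return FreqVector(p=p, n=fv.n)


def make_windows(vt: VariantTable, size_bp: int, step_bp: int,
                 min_snps: int = 0, chrom_lengths: dict | None = None,
                 ) -> pd.DataFrame:
    """Sliding windows anchored at position 1 on every chromosome.

    Windows are ``[k*step+1, k*step+size]`` (1-based inclusive) for every k
    with start on the chromosome, the last ones truncated at the chromosome
    end. Windows with fewer than ``min_snps`` records are flagged
    ``excluded`` but still emitted.

    Returns a DataFrame with columns chrom, start, end, n_snps, excluded.
    """
    if not (size_bp >= step_bp >= 1):
        raise ValueError("require size_bp >= step_bp >= 1")
    rows = []
    for c in vt.chromosomes():
        length = (chrom_lengths or {}).get(c) or vt.chrom_length(c)
        pos = vt.pos[vt.chrom == c]
        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + size_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        nsnp = hi - lo
        for s, e, k in zip(starts, ends, nsnp):
            rows.append((c, int(s), int(e), int(k), bool(k < min_snps)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "excluded"])


def windows_to_bed(windows: pd.DataFrame, path, score_col: str | None = None,
                   ) -> None:
    """Write windows/regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in windows.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1),
                      str(int(row["end"]))]
            if score_col is not None:
                fields += [".", f"{row[score_col]:.6g}"]
            fh.write("\t".join(fields) + "\n")


def read_gff_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Only ``gene`` records are kept; the identifier is the ``ID`` or ``Name``
    attribute, else a positional label. Returns columns chrom, start, end,
    gene_id (1-based inclusive coordinates, GFF convention).
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line {i + 1}")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"gene{i}"
            rows.append((parts[0], int(parts[3]), int(parts[4]), gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
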