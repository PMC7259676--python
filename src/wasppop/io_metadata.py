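"""Core data model and file IO: genotype matrices from VCF, mitochondrial
haplotype alignments from FASTA, sample metadata from TSV, and the variant
filters (missingness, minor-allele count, physical thinning) applied before
every downstream analysis.

Genotypes are stored as alt-allele dosage (0, 1, 2; ``-1`` = missing call).
Phase is discarded: every statistic downstream is allele-frequency based.
Positions are 1-based (VCF convention); genomic windows are half-open
``[start, start + window)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleTable",
    "HaplotypeSet",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "thin_sites",
    "read_haplotypes",
    "write_haplotypes",
    "read_metadata",
    "write_metadata",
]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted as a diploid GT call."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP sites, calls coded as alt-allele dosage.

    Attributes
    ----------
    sample_ids : list of str
        Sample identifiers, in VCF column order.
    chrom : ndarray of str, shape (n_sites,)
    pos : ndarray of int, shape (n_sites,)
        1-based positions, strictly increasing within each chromosome.
    ref, alt : ndarray of str, shape (n_sites,)
        Single-base reference and alternate alleles.
    calls : ndarray of int8, shape (n_samples, n_sites)
        0/1/2 alt-allele dosage; ``MISSING`` (-1) for uncalled genotypes.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n_samples, n_sites = self.calls.shape
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"calls has {n_samples} rows but {len(self.sample_ids)} sample ids"
            )
        if n_sites != len(self.pos):
            raise ValueError(
                f"calls has {n_sites} columns but {len(self.pos)} site records"
            )
        for arr, name in ((self.chrom, "chrom"), (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length {len(arr)} != n_sites {n_sites}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [lookup[s] for s in ids]
        return replace(self, sample_ids=list(ids), calls=self.calls[idx, :])

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site over non-missing calls (NaN if none)."""
        called = self.calls != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


@dataclass
class SampleTable:
    """Per-sample coordinates and grouping labels.

    Wraps a DataFrame with columns: sample_id, site_label, region_label,
    latitude, longitude, year, and optional building_label / region_radius_km.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "site_label", "region_label", "latitude", "longitude", "year")
    OPTIONAL = ("building_label", "region_radius_km")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        lat = self.df["latitude"].astype(float)
        lon = self.df["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def subset(self, ids: list[str]) -> "SampleTable":
        sub = self.df[self.df["sample_id"].isin(set(ids))]
        return SampleTable(sub.copy())

    def groups(self, label: str = "region_label") -> dict[str, list[str]]:
        """Map group label -> member sample ids, in table order."""
        out: dict[str, list[str]] = {}
        for sid, g in zip(self.df["sample_id"], self.df[label]):
            out.setdefault(str(g), []).append(sid)
        return out


@dataclass
class HaplotypeSet:
    """Aligned haploid sequences (concatenated mitochondrial genes).

    All sequences share one length; ``gene_boundaries`` optionally records
    (gene name, start, end) half-open segments tiling the concatenation.
    """

    sample_ids: list[str]
    sequences: list[str]
    gene_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        if self.gene_boundaries:
            bounds = sorted(self.gene_boundaries, key=lambda g: g[1])
            pos = 0
            for name, start, end in bounds:
                if start != pos or end <= start:
                    raise ValueError("gene segments must tile the alignment without overlap")
                pos = end
            if self.sequences and pos != self.length:
                raise ValueError("gene segments do not cover the full alignment")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def subset(self, ids: list[str]) -> "HaplotypeSet":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in ids]
        return HaplotypeSet(list(ids), [self.sequences[i] for i in idx], list(self.gene_boundaries))

    def to_codes(self) -> np.ndarray:
        """Encode as uint8 codes A,C,G,T -> 0..3; anything else -> 255."""
        table = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            table[b] = i
            table[b + 32] = i  # lowercase
        raw = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return table[raw].reshape(self.n, self.length)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNPs (indels, symbolic alleles) are dropped
    when ``biallelic_only`` is set. Missing genotypes (``./.``) map to
    :data:`MISSING`. Sample order follows the VCF header.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        if not sample_ids:
            raise ValueError(f"{path}: VCF contains no samples")
        chroms, positions, refs, alts, rows = [], [], [], [], []
        for rec in vcf:
            alleles = rec.alleles
            if alleles is None or len(alleles) < 2:
                continue
            is_biallelic_snp = (
                len(alleles) == 2
                and len(alleles[0]) == 1
                and len(alleles[1]) == 1
                and alleles[1] in "ACGT"
            )
            if biallelic_only and not is_biallelic_snp:
                continue
            row = np.empty(len(sample_ids), dtype=np.int8)
            for i, sid in enumerate(sample_ids):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = MISSING
                else:
                    if any(a not in (0, 1) for a in gt):
                        raise VcfParseError(
                            f"{path}:{rec.chrom}:{rec.pos}: allele index out of "
                            f"range for a biallelic site in sample {sid}"
                        )
                    row[i] = sum(gt)
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            refs.append(alleles[0])
            alts.append(alleles[1])
            rows.append(row)
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with unphased GT calls only (no INFO annotations)."""
    path = Path(path)
    header = pysam.VariantHeader()
    contigs = list(dict.fromkeys(g.chrom))  # preserve first-seen order
    for c in contigs:
        length = int(g.pos[g.chrom == c].max()) + 1 if g.n_sites else 1
        header.contigs.add(str(c), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in g.sample_ids:
        header.add_sample(sid)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(g.n_sites):
            rec = out.new_record(
                contig=str(g.chrom[j]),
                start=int(g.pos[j]) - 1,
                alleles=(str(g.ref[j]), str(g.alt[j])),
            )
            for i, sid in enumerate(g.sample_ids):
                rec.samples[sid]["GT"] = gt_map[int(g.calls[i, j])]
                rec.samples[sid].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# Variant filters


def filter_sites(g: GenotypeMatrix, max_missing: float = 0.8, min_mac: int = 3) -> GenotypeMatrix:
    """Apply the missingness and minor-allele-count site filters.

    A site survives iff the fraction of non-missing genotypes is >=
    ``max_missing`` (the VCFtools ``--max-missing`` convention: a *minimum*
    call-rate, boundary inclusive) AND the minor-allele count over
    non-missing calls is >= ``min_mac`` (boundary inclusive; ``--mac 3``
    keeps count 3). The sample set is unchanged. An empty result warns
    rather than raises.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    called = g.calls != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / max(g.n_samples, 1)
    alt_count = np.where(called, g.calls, 0).sum(axis=0)
    total_alleles = 2 * n_called
    mac = np.minimum(alt_count, total_alleles - alt_count)
    keep = (call_rate >= max_missing) & (mac >= min_mac)
    if not keep.any():
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return g.take_sites(keep)


def thin_sites(g: GenotypeMatrix, window_bp: int = 10_000) -> GenotypeMatrix:
    """Physically thin to at most one SNP per ``window_bp``.

    Greedy left-to-right per chromosome: the first site of each chromosome
    is always kept; a later site is kept iff its position is at least
    ``window_bp`` past the last kept position. Deterministic.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    keep = np.zeros(g.n_sites, dtype=bool)
    last_kept: dict[str, int] = {}
    for j in range(g.n_sites):
        c, p = g.chrom[j], int(g.pos[j])
        if c not in last_kept or p >= last_kept[c] + window_bp:
            keep[j] = True
            last_kept[c] = p
    return g.take_sites(keep)


# ---------------------------------------------------------------------------
# FASTA haplotypes


def read_haplotypes(path: str | Path, gene_map: str | Path | None = None) -> HaplotypeSet:
    """Read aligned per-sample haplotype sequences from FASTA.

    ``gene_map`` is an optional TSV (columns gene, start, end; half-open,
    0-based) recording the concatenated gene segments.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError(f"{path}: sequences are not aligned (unequal lengths)")
    boundaries: list[tuple[str, int, int]] = []
    if gene_map is not None:
        gm = pd.read_csv(gene_map, sep="\t")
        boundaries = [
            (str(r.gene), int(r.start), int(r.end)) for r in gm.itertuples(index=False)
        ]
    return HaplotypeSet(ids, seqs, boundaries)


def write_haplotypes(h: HaplotypeSet, path: str | Path, gene_map: str | Path | None = None) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in zip(h.sample_ids, h.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
    if gene_map is not None and h.gene_boundaries:
        pd.DataFrame(h.gene_boundaries, columns=["gene", "start", "end"]).to_csv(
            gene_map, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Metadata TSV  (tab-separated, header required, '.' = missing optional field)


def read_metadata(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["."])
    return SampleTable(df)


def write_metadata(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep=".")
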