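"""Readers, writers and shared genomic domain types.

All internal coordinates are 0-based half-open (BED convention); 1-based
variant-file positions are converted on ingestion.  Loaders sort their
output so that the in-memory state is independent of input row order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tfbs_indel_scan")

MISSING = -1  # sentinel for an uncalled genotype dosage
UNASSIGNED = "unassigned"  # population label for samples absent from the map

SELECTION_TRACK_COLUMNS = ("chrom", "start", "end", "metric", "population", "ranked_p")


class ParseError(ValueError):
    """A malformed row in an input file (message carries the line number)."""


class ValidationError(ValueError):
    """A well-formed value violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True, order=True)
class TfbsPeak:
    """A ChIP-seq binding-site peak labelled with its transcription factor."""

    interval: GenomicInterval
    tf_name: str
    source_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValidationError("tf_name must be non-empty")


@dataclass(frozen=True)
class IndelVariant:
    """A biallelic insertion or deletion in left-anchored VCF representation.

    ``pos`` is the 1-based anchor position as written in the variant file;
    the anchor base itself is unchanged sequence, so the first base that
    differs from the reference sits one base to its right.
    """

    chrom: str
    pos: int  # 1-based anchor
    ref_allele: str
    alt_allele: str
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValidationError(
                f"{self.chrom}:{self.pos} ref/alt of equal length is not an indel"
            )
        if self.pos < 1:
            raise ValidationError("variant position must be >= 1")

    @property
    def indel_type(self) -> str:
        return "DEL" if len(self.ref_allele) > len(self.alt_allele) else "INS"

    @property
    def length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> str:
        """Stable identifier; falls back to coordinates when the ID is missing."""
        if self.variant_id and self.variant_id != ".":
            return self.variant_id
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"

    def first_affected_base(self, rule: str = "first-changed") -> int:
        """0-based position of the event start.

        ``first-changed`` (default): the base after the anchor — the first
        base actually altered.  ``anchor``: the VCF POS itself, 0-based,
        for sensitivity analysis.
        """
        if rule == "first-changed":
            return self.pos  # (pos - 1) 0-based anchor, + 1
        if rule == "anchor":
            return self.pos - 1
        raise ValueError(f"unknown begin rule {rule!r}")


@dataclass
class GenotypeMatrix:
    """Per-sample alternate-allele dosages for a set of indel variants."""

    variants: list[IndelVariant]
    samples: list[str]
    dosage: np.ndarray  # (n_variants, n_samples), values in {0,1,2,MISSING}
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosage values must be in {0, 1, 2, missing}")
        for s in self.samples:
            self.population_of.setdefault(s, UNASSIGNED)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        """Assigned population labels, sorted; excludes 'unassigned'."""
        labels = {self.population_of[s] for s in self.samples}
        labels.discard(UNASSIGNED)
        return sorted(labels)

    def sample_indices(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.population_of[s] == population],
            dtype=int,
        )

    def variant_index(self, key: str) -> int:
        for i, v in enumerate(self.variants):
            if v.key == key:
                return i
        raise KeyError(key)


@dataclass(frozen=True)
class GeneModel:
    """Largest-transcript span of a gene with its strand-aware TSS."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        """0-based transcription start site."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values."""

    genes: list[str]
    samples: list[str]
    fpkm: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("fpkm shape does not match genes x samples")
        if np.any(self.fpkm < 0) or not np.all(np.isfinite(self.fpkm)):
            raise ValidationError("FPKM values must be finite and non-negative")

    def row(self, gene_id: str) -> np.ndarray:
        return self.fpkm[self.genes.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpkm, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class SelectionRecord:
    interval: GenomicInterval
    metric: str
    population: str
    ranked_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ranked_p <= 1.0):
            raise ValidationError(f"ranked_p {self.ranked_p} outside [0, 1]")


@dataclass
class SelectionTrack:
    """Intervals scored with genome-rank p-values per selection metric and population."""

    records: list[SelectionRecord]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(path: str | Path, dialect: str = "bed") -> list[TfbsPeak]:
    """Load TF-labelled peaks from BED4+ or ENCODE narrowPeak.

    The name column carries the TF label.  Exact duplicates of
    (interval, tf_name) are collapsed; output is coordinate-sorted.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 4 if dialect == "bed" else 10
    seen: dict[tuple, TfbsPeak] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < min_cols:
            raise ParseError(
                f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
            )
        chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
        try:
            iv = GenomicInterval(chrom, int(start), int(end))
        except ValueError as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from None
        peak = TfbsPeak(iv, name)
        seen.setdefault((iv.chrom, iv.start, iv.end, name), peak)
    return sorted(seen.values())


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample ID, population label."""
    mapping: dict[str, str] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        mapping[fields[0]] = fields[1]
    return mapping


def read_indel_genotypes(path: str | Path, sample_map: str | Path) -> GenotypeMatrix:
    """Load indel rows from a VCF with GT fields into a GenotypeMatrix.

    SNVs (equal ref/alt length) are dropped.  Multi-allelic rows are split
    into one record per alternate allele, with dosages recoded as the count
    of that allele.  Samples absent from the map get the 'unassigned' label
    (with a warning) and are excluded from population statistics downstream.
    """
    from cyvcf2 import VCF

    pop_of = read_sample_map(sample_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in pop_of]
    if unmapped:
        logger.warning(
            "%d sample(s) absent from population map, labelled %r: %s",
            len(unmapped), UNASSIGNED, ", ".join(unmapped[:5]),
        )
    variants: list[IndelVariant] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        gts = v.genotypes  # [a0, a1, phased] per sample
        for ai, alt in enumerate(v.ALT, start=1):
            if len(alt) == len(v.REF):
                continue  # substitution against this allele
            dos = np.empty(len(samples), dtype=np.int8)
            for si, g in enumerate(gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    dos[si] = MISSING
                else:
                    dos[si] = sum(1 for a in alleles if a == ai)
            variants.append(
                IndelVariant(v.CHROM, v.POS, v.REF, alt, v.ID)
            )
            rows.append(dos)
    if not variants:
        logger.warning("%s: no indel rows found; returning an empty matrix", path)
        return GenotypeMatrix([], samples, np.empty((0, len(samples)), np.int8),
                              {s: pop_of.get(s, UNASSIGNED) for s in samples})
    order = sorted(range(len(variants)),
                   key=lambda i: (variants[i].chrom, variants[i].pos, variants[i].key))
    return GenotypeMatrix(
        [variants[i] for i in order],
        samples,
        np.vstack([rows[i] for i in order]),
        {s: pop_of.get(s, UNASSIGNED) for s in samples},
    )


def read_genes(path: str | Path) -> list[GeneModel]:
    """TSV of gene_id, chrom, start, end, strand; TSS derived from strand."""
    genes: list[GeneModel] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns")
        gene_id, chrom, start, end, strand = fields[:5]
        try:
            genes.append(GeneModel(gene_id, GenomicInterval(chrom, int(start), int(end)), strand))
        except ValueError as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from None
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV matrix: rows = genes, columns = samples, values = FPKM."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_selection_track(path: str | Path) -> SelectionTrack:
    """TSV with header: chrom, start, end, metric, population, ranked_p."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SELECTION_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = [
        SelectionRecord(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            str(r.metric), str(r.population), float(r.ranked_p),
        )
        for r in df.itertuples()
    ]
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.metric, r.population))
    return SelectionTrack(records)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: category, description, member genes (tab-separated)."""
    categories: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT rows need >= 3 columns")
        categories[fields[0]] = set(fields[2:])
    return categories


# ---------------------------------------------------------------------------
# Writers (the synthetic generator emits exactly these dialects)
# ---------------------------------------------------------------------------

def write_peaks(peaks: Sequence[TfbsPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks):
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.tf_name}\n")


def write_sample_map(population_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in population_of.items():
            fh.write(f"{sample}\t{pop}\n")


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    chroms = sorted({v.chrom for v in matrix.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for v, row in zip(matrix.variants, matrix.dosage):
            gts = "\t".join(_GT_STRING[int(d)] for d in row)
            vid = v.variant_id or "."
            fh.write(f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.interval.chrom}\t{g.interval.start}"
                     f"\t{g.interval.end}\t{g.strand}\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_selection_track(track: SelectionTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SELECTION_TRACK_COLUMNS) + "\n")
        for r in track.records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                     f"\t{r.metric}\t{r.population}\t{r.ranked_p:.6g}\n")


def write_gmt(categories: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(categories):
            members = "\t".join(sorted(categories[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
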