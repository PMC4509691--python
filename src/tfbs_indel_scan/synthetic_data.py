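"""Synthetic cohorts with injectable ground-truth effects.

Generates a coherent bundle — TF peaks near gene TSSs, population-stratified
indel genotypes, an FPKM expression matrix with optional cis effects, a flat
gene-category annotation and a ranked-p selection track — in exactly the
file dialects the readers consume, so every downstream stage is testable
without consortium downloads.

Model: genotypes are drawn binomially per population from per-variant
allele frequencies (Hardy–Weinberg equilibrium within population, no
linkage disequilibrium except what swept regions inject); expression is
lognormal around a per-gene baseline, with injected cis effects acting
additively on log-FPKM per dosage unit; swept regions resample the
genotypes of focal-allele carriers from frequencies pulled toward fixation
so that their expected heterozygosity is reduced by a stated factor, and
the selection track marks those regions with low rank p-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data_io
from .data_io import (
    ExpressionMatrix, GeneModel, GenomicInterval, GenotypeMatrix,
    IndelVariant, SelectionRecord, SelectionTrack, TfbsPeak,
)

TF_POOL = ("CTCF", "POLR2A", "MYC", "JUN", "GATA1", "SPI1",
           "STAT1", "NFKB1", "TP53", "EGR1", "YY1", "MAX")
SELECTION_METRICS = ("CLR", "FayWuH", "FuLiD", "R2", "TajimaD")
_BASES = np.array(list("ACGT"))


@dataclass
class CohortSpec:
    """Cohort dimensions and nuisance parameters.

    Defaults follow the three-continent design of the study system: 246
    African, 379 European and 286 Asian samples, indel lengths geometric
    with mean 3 bp (indel length spectra are strongly skewed to a few bp),
    70 % of indels seeded to start inside a peak, log-FPKM noise SD 0.5.
    """

    n_samples_per_population: dict[str, int] = field(
        default_factory=lambda: {"AFR": 246, "EUR": 379, "ASN": 286})
    n_genes: int = 30
    n_peaks_per_gene: int = 3
    n_indels: int = 150
    indel_mean_len: float = 3.0
    frac_in_peak: float = 0.7
    gene_spacing: int = 50_000
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples_per_population or \
                any(n < 1 for n in self.n_samples_per_population.values()):
            raise ValueError("every population needs >= 1 sample")
        if min(self.n_genes, self.n_peaks_per_gene, self.n_indels) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class EffectSpec:
    """Ground-truth effects to inject.

    differentiated_variants: (variant index, {population: target frequency});
    cis_effects: (gene_id, variant index, effect on log-FPKM per dosage unit);
    swept_regions: (interval, heterozygosity reduction factor in (0, 1],
    focal variant index).  Variant indices refer to position-sorted order.
    """

    differentiated_variants: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    cis_effects: list[tuple[str, int, float]] = field(default_factory=list)
    swept_regions: list[tuple[GenomicInterval, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, freqs in self.differentiated_variants:
            if any(not 0.0 <= f <= 1.0 for f in freqs.values()):
                raise ValueError("target frequencies must lie in [0, 1]")
        for _, _, beta in self.cis_effects:
            if not np.isfinite(beta):
                raise ValueError("cis effect sizes must be finite")


@dataclass
class Cohort:
    """In-memory bundle mirroring one file bundle."""

    peaks: list[TfbsPeak]
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    expression: ExpressionMatrix
    categories: dict[str, set[str]]
    track: SelectionTrack
    true_frequencies: np.ndarray  # (n_variants, n_populations), population order sorted

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / "peaks.bed",
            "vcf": outdir / "indels.vcf",
            "sample_map": outdir / "samples.tsv",
            "genes": outdir / "genes.tsv",
            "expression": outdir / "expression.tsv",
            "gmt": outdir / "categories.gmt",
            "track": outdir / "selection_track.tsv",
        }
        data_io.write_peaks(self.peaks, paths["peaks"])
        data_io.write_vcf(self.genotypes, paths["vcf"])
        data_io.write_sample_map(self.genotypes.population_of, paths["sample_map"])
        data_io.write_genes(self.genes, paths["genes"])
        data_io.write_expression(self.expression, paths["expression"])
        data_io.write_gmt(self.categories, paths["gmt"])
        data_io.write_selection_track(self.track, paths["track"])
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _reduced_frequency(f: float, factor: float) -> float:
    """Frequency with expected heterozygosity scaled by ``factor``, on the
    same side of 0.5 as ``f``."""
    h = factor * 2.0 * f * (1.0 - f)
    s = np.sqrt(max(0.0, 1.0 - 2.0 * h))
    return (1.0 - s) / 2.0 if f <= 0.5 else (1.0 + s) / 2.0


def simulate_cohort(
    spec: CohortSpec, effects: EffectSpec | None = None
) -> Cohort:
    """Draw one cohort; identical spec (and seed) gives an identical cohort."""
    effects = effects or EffectSpec()
    rng = np.random.default_rng(spec.seed)
    pops = sorted(spec.n_samples_per_population)
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    for pop in pops:
        for i in range(spec.n_samples_per_population[pop]):
            s = f"{pop}{i:04d}"
            samples.append(s)
            pop_of[s] = pop

    # --- gene models, evenly spaced with jitter, random strand
    genes: list[GeneModel] = []
    for gi in range(spec.n_genes):
        start = 20_000 + gi * spec.gene_spacing + int(rng.integers(0, 2_000))
        length = int(rng.integers(8_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{gi:04d}",
                               GenomicInterval(spec.chrom, start, start + length), strand))

    # --- peaks in the 5 kb upstream of each TSS
    peaks: list[TfbsPeak] = []
    for g in genes:
        for _ in range(spec.n_peaks_per_gene):
            width = int(rng.integers(150, 300))
            u = int(rng.integers(200, 4_800 - width))
            if g.strand == "+":
                start = g.tss - u - width
            else:
                start = g.tss + u
            peaks.append(TfbsPeak(GenomicInterval(spec.chrom, start, start + width),
                                  str(rng.choice(TF_POOL))))
    peaks = sorted(set(peaks))

    # --- indel positions: a stated fraction begin inside a peak
    n_seeded = int(round(spec.frac_in_peak * spec.n_indels))
    extent = 20_000 + spec.n_genes * spec.gene_spacing + 20_000
    positions: list[int] = []
    for _ in range(n_seeded):
        p = peaks[int(rng.integers(len(peaks)))]
        positions.append(int(rng.integers(p.interval.start, p.interval.end)))
    positions += [int(rng.integers(1_000, extent))
                  for _ in range(spec.n_indels - n_seeded)]
    positions.sort()

    variants: list[IndelVariant] = []
    for vi, b in enumerate(positions):
        length = min(199, int(rng.geometric(1.0 / spec.indel_mean_len)))
        anchor = _random_seq(rng, 1)
        inserted = _random_seq(rng, length)
        if rng.random() < 0.5:
            ref, alt = anchor + inserted, anchor   # deletion
        else:
            ref, alt = anchor, anchor + inserted   # insertion
        # first affected base b corresponds to 1-based anchor POS = b
        variants.append(IndelVariant(spec.chrom, b, ref, alt, f"rs{900000 + vi}"))

    # --- per-population allele frequencies
    base = rng.uniform(0.05, 0.95, size=spec.n_indels)
    freq = np.tile(base[:, None], (1, len(pops)))
    for idx, targets in effects.differentiated_variants:
        for pop, f in targets.items():
            freq[idx, pops.index(pop)] = f

    # --- Hardy-Weinberg genotypes
    dosage = np.empty((spec.n_indels, len(samples)), dtype=np.int8)
    col = 0
    pop_cols: dict[str, slice] = {}
    for j, pop in enumerate(pops):
        n = spec.n_samples_per_population[pop]
        pop_cols[pop] = slice(col, col + n)
        dosage[:, col:col + n] = rng.binomial(2, freq[:, j][:, None],
                                              size=(spec.n_indels, n))
        col += n

    # --- swept regions: carriers of the focal allele lose diversity
    for interval, factor, focal_idx in effects.swept_regions:
        if not 0.0 < factor <= 1.0:
            raise ValueError("heterozygosity reduction factor must be in (0, 1]")
        carriers = np.flatnonzero(dosage[focal_idx] == 2)
        for vi, v in enumerate(variants):
            if vi == focal_idx or not interval.contains(v.first_affected_base()):
                continue
            f_red = _reduced_frequency(float(freq[vi].mean()), factor)
            dosage[vi, carriers] = rng.binomial(2, f_red, size=carriers.size)

    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = data_io.MISSING

    genotypes = GenotypeMatrix(variants, samples, dosage, dict(pop_of))

    # --- expression: lognormal baseline, cis effects additive on log-FPKM
    log_f = rng.normal(2.0, 1.0, size=spec.n_genes)[:, None] \
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))
    gene_row = {g.gene_id: i for i, g in enumerate(genes)}
    for gene_id, vidx, beta in effects.cis_effects:
        dos = np.where(dosage[vidx] == data_io.MISSING, 0, dosage[vidx])
        log_f[gene_row[gene_id]] += beta * dos
    expression = ExpressionMatrix([g.gene_id for g in genes], samples, np.exp(log_f))

    # --- flat categories over genes
    gene_ids = [g.gene_id for g in genes]
    categories: dict[str, set[str]] = {}
    n_cat = max(3, min(10, spec.n_genes // 3))
    for ci in range(n_cat):
        size = int(rng.integers(3, max(4, spec.n_genes // 2)))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        categories[f"category{ci:02d}"] = set(members)

    # --- selection track: 10 kb tiles, uniform rank p, low p over swept regions
    swept = [iv for iv, _, _ in effects.swept_regions]
    records: list[SelectionRecord] = []
    for start in range(0, extent, 10_000):
        tile = GenomicInterval(spec.chrom, start, start + 10_000)
        in_sweep = any(tile.start < s.end and s.start < tile.end for s in swept)
        for metric in SELECTION_METRICS:
            for pop in pops:
                p = rng.uniform(0.0, 0.009) if in_sweep else rng.uniform(0.01, 1.0)
                records.append(SelectionRecord(tile, metric, pop, float(p)))
    track = SelectionTrack(records)

    return Cohort(peaks, genotypes, genes, expression, categories, track, freq)


def generate_cohort(
    spec: CohortSpec, effects: EffectSpec | None = None,
    outdir: str | Path = "cohort",
) -> dict[str, Path]:
    """Simulate a cohort and write the full file bundle; returns the paths."""
    return simulate_cohort(spec, effects).write(outdir)


def worked_fixture(outdir: str | Path | None = None) -> Cohort | dict[str, Path]:
    """Minimal deterministic cohort realizing the canonical worked example.

    One 2 bp deletion (rs139999735-like coordinates are synthetic) starts
    inside a single NFKB1 peak 2 kb upstream of a plus-strand gene.  With 50
    samples per population the emitted genotypes give derived-allele
    frequencies of exactly 0.34 (AFR), 0.11 (ASN) and 0.12 (EUR), hence
    δ(AFR) = 0.34 − 0.12 = 0.22.  Expression decreases deterministically
    with dosage and a track tile covering the variant carries rank p < 0.01.

    Returns the in-memory Cohort, or the file-path bundle when ``outdir``
    is given.
    """
    chrom = "chr1"
    b = 10_000  # first affected base, 0-based
    variant = IndelVariant(chrom, b, "CAT", "C", "rs139999735")
    peak = TfbsPeak(GenomicInterval(chrom, 9_900, 10_100), "NFKB1")
    gene = GeneModel("geneA", GenomicInterval(chrom, 12_000, 22_000), "+")

    alt_counts = {"AFR": 34, "ASN": 11, "EUR": 12}  # of 100 chromosomes each
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    dosages: list[int] = []
    for pop in sorted(alt_counts):
        c = alt_counts[pop]
        per_sample = [2] * (c // 2) + [1] * (c % 2)
        per_sample += [0] * (50 - len(per_sample))
        for i, d in enumerate(per_sample):
            s = f"{pop}{i:04d}"
            samples.append(s)
            pop_of[s] = pop
            dosages.append(d)
    dosage = np.array(dosages, dtype=np.int8)[None, :]
    genotypes = GenotypeMatrix([variant], samples, dosage, pop_of)

    fpkm = np.array([[12.0 - 2.0 * d + 0.01 * i for i, d in enumerate(dosages)]])
    expression = ExpressionMatrix(["geneA"], samples, fpkm)
    categories = {"apoptotic_process": {"geneA"}, "ion_transport": {"geneB"}}
    track = SelectionTrack([
        SelectionRecord(GenomicInterval(chrom, 5_000, 15_000), "CLR", "AFR", 0.005),
        SelectionRecord(GenomicInterval(chrom, 15_000, 25_000), "CLR", "AFR", 0.5),
    ])
    freq = np.array([[0.34, 0.11, 0.12]])  # AFR, ASN, EUR (sorted)
    cohort = Cohort([peak], genotypes, [gene], expression, categories, track, freq)
    if outdir is not None:
        return cohort.write(outdir)
    return cohort
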