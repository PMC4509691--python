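"""Identification of TFBS-affecting indels (TFBS-ID) and TSS-window annotation.

An indel "affects" a binding site when its first affected base — the base
after the VCF anchor, i.e. the first base that actually differs from the
reference — lies inside the peak interval.  Requiring the event to *begin*
inside the peak precludes counting a long deletion that merely spans a site.
Affected indels are then assigned to genes whose TSS lies within an analysis
window: 5 kb upstream of the TSS on the transcription strand, or 2.5 kb on
each side of the TSS.
"""
from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .data_io import GeneModel, GenotypeMatrix, TfbsPeak

WINDOW_UPSTREAM = "upstream5k"
WINDOW_FLANKING = "flanking5k"
UPSTREAM_SPAN = 5000
FLANKING_HALF_SPAN = 2500


@dataclass
class TfbsIdRecord:
    """One TFBS-affecting indel with all peaks it starts inside.

    ``position`` is the 0-based first affected base used for every
    downstream coordinate query (window assignment, selection matching).
    ``gene_assignments`` holds (gene, window class, signed distance to TSS)
    triples; distance is negative upstream of the TSS on the transcription
    strand and positive downstream.
    """

    indel: "IndelVariant"
    position: int
    affected_peaks: list[TfbsPeak]
    gene_assignments: list[tuple[GeneModel, str, int]] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.indel.chrom


@dataclass
class OverlapSummary:
    """Redundancy and positional summary of a TFBS-ID set.

    ``n_tfbs_affected`` counts (peak, indel) associations — the same peak
    hit by two indels, or one indel hitting two overlapping peaks, counts
    twice — while ``n_unique_indels`` counts distinct TFBS-ID.
    """

    n_tfbs_affected: int
    n_unique_indels: int
    per_tf_counts: dict[str, int] = field(default_factory=dict)
    position_histogram: dict[str, tuple[list[float], list[int]]] = field(default_factory=dict)

    @property
    def mean_tfbs_per_indel(self) -> float:
        if self.n_unique_indels == 0:
            return 0.0
        return self.n_tfbs_affected / self.n_unique_indels


def find_tfbs_id(
    peaks: list[TfbsPeak],
    genotypes: GenotypeMatrix,
    max_len: int = 200,
    begin_rule: str = "first-changed",
) -> list[TfbsIdRecord]:
    """Match indels shorter than ``max_len`` to the peaks they begin inside.

    Returns one coordinate-sorted record per matching indel, aggregating all
    peaks whose interval contains the indel's first affected base.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.interval.chrom].addi(p.interval.start, p.interval.end, p)
    records: list[TfbsIdRecord] = []
    n_no_chrom = 0
    for variant in genotypes.variants:
        if variant.length >= max_len:
            continue
        tree = trees.get(variant.chrom)
        if tree is None:
            n_no_chrom += 1
            continue
        b = variant.first_affected_base(begin_rule)
        hits = sorted((iv.data for iv in tree.at(b)))
        if hits:
            records.append(TfbsIdRecord(variant, b, hits))
    if n_no_chrom:
        from .data_io import logger
        logger.info("%d variant(s) on chromosomes with no peaks", n_no_chrom)
    records.sort(key=lambda r: (r.chrom, r.position, r.indel.key))
    return records


def signed_tss_distance(position: int, gene: GeneModel) -> int:
    """Strand-aware signed distance from ``position`` to the gene's TSS.

    Negative upstream of the TSS (against transcription), positive
    downstream, zero at the TSS itself.
    """
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position


def in_window(distance: int, window: str) -> bool:
    if window == WINDOW_UPSTREAM:
        # TSS-proximal edge inclusive (d = 0), half-open at the far edge.
        return -UPSTREAM_SPAN < distance <= 0
    if window == WINDOW_FLANKING:
        return -FLANKING_HALF_SPAN < distance < FLANKING_HALF_SPAN
    raise ValueError(f"unknown window {window!r}")


def assign_genes(
    records: list[TfbsIdRecord],
    genes: list[GeneModel],
    window: str = WINDOW_UPSTREAM,
) -> list[TfbsIdRecord]:
    """Fill gene_assignments for every record whose position falls in the
    window anchored at a gene's TSS.  One indel may be assigned to several
    genes; assignments for other windows already present are kept."""
    if window not in (WINDOW_UPSTREAM, WINDOW_FLANKING):
        raise ValueError(f"unknown window {window!r}")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.interval.chrom].append(g)
    tss_sorted = {
        c: sorted(gs, key=lambda g: (g.tss, g.gene_id)) for c, gs in by_chrom.items()
    }
    tss_keys = {c: [g.tss for g in gs] for c, gs in tss_sorted.items()}
    span = UPSTREAM_SPAN if window == WINDOW_UPSTREAM else FLANKING_HALF_SPAN
    for rec in records:
        gs = tss_sorted.get(rec.chrom)
        if not gs:
            continue
        keys = tss_keys[rec.chrom]
        lo = bisect.bisect_left(keys, rec.position - span)
        hi = bisect.bisect_right(keys, rec.position + span)
        for g in gs[lo:hi]:
            d = signed_tss_distance(rec.position, g)
            if in_window(d, window):
                rec.gene_assignments.append((g, window, d))
    return records


def summarize(records: list[TfbsIdRecord], n_bins: int = 10) -> OverlapSummary:
    """Counts, per-TF tallies and relative-position histograms of a TFBS-ID set.

    The histogram bins signed TSS distances of gene assignments into
    ``n_bins`` equal-width bins spanning each window.  Empty input yields a
    zero summary.
    """
    n_assoc = sum(len(r.affected_peaks) for r in records)
    per_tf: Counter[str] = Counter()
    for r in records:
        for p in r.affected_peaks:
            per_tf[p.tf_name] += 1
    ranges = {WINDOW_UPSTREAM: (-UPSTREAM_SPAN, 0),
              WINDOW_FLANKING: (-FLANKING_HALF_SPAN, FLANKING_HALF_SPAN)}
    distances: dict[str, list[int]] = defaultdict(list)
    for r in records:
        for _, wc, d in r.gene_assignments:
            distances[wc].append(d)
    histogram: dict[str, tuple[list[float], list[int]]] = {}
    for wc, ds in distances.items():
        lo, hi = ranges[wc]
        counts, edges = np.histogram(ds, bins=n_bins, range=(lo, hi))
        histogram[wc] = (edges.tolist(), counts.tolist())
    return OverlapSummary(
        n_tfbs_affected=n_assoc,
        n_unique_indels=len(records),
        per_tf_counts=dict(per_tf),
        position_histogram=histogram,
    )
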