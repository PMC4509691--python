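"""Positive-selection evidence for TFBS-affecting indels.

Two independent lines of evidence are computed: (a) matching each TFBS-ID
against external selection-score tracks — intervals carrying genome-rank
p-values for sweep statistics such as CLR or Tajima's D — where rank
p < 0.05 in any metric or population marks 95 % confidence and p < 0.01
marks 99 %; and (b) a genotype-stratified sweep profile, the sliding-window
expected heterozygosity 2p(1−p) of flanking variants computed separately in
samples homozygous for the focal indel and samples homozygous for its
absence.  A selective sweep carrying the indel depresses diversity in
carriers, so the carrier curve runs below the non-carrier curve around the
focal position.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .data_io import MISSING, GenotypeMatrix, IndelVariant, SelectionTrack, logger
from .tfbs_overlap import TfbsIdRecord

C95, C99, NONE = "c95", "c99", "none"


@dataclass
class SelectionMatch:
    variant_id: str
    matched: list[tuple[str, str, float]]  # (metric, population, ranked_p)

    @property
    def min_ranked_p(self) -> float | None:
        return min((p for *_, p in self.matched), default=None)

    @property
    def confidence_class(self) -> str:
        p = self.min_ranked_p
        if p is None or p >= 0.05:
            return NONE
        return C99 if p < 0.01 else C95


@dataclass
class MatchSummary:
    n_records: int
    n_c95: int  # min ranked_p < 0.05 (includes the c99 subset)
    n_c99: int  # min ranked_p < 0.01

    @property
    def fraction_c95(self) -> float:
        return self.n_c95 / self.n_records if self.n_records else 0.0

    @property
    def fraction_c99(self) -> float:
        return self.n_c99 / self.n_records if self.n_records else 0.0


def match_selection(
    records: list[TfbsIdRecord], track: SelectionTrack
) -> tuple[list[SelectionMatch], MatchSummary]:
    """Point-query every TFBS-ID's first affected base against the track.

    A record matches at 95 % confidence when any covering interval has
    ranked_p < 0.05 (strict) for any metric/population, at 99 % when < 0.01.
    """
    if not track.records:
        logger.warning("empty selection track: no record can match")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in track.records:
        trees[r.interval.chrom].addi(r.interval.start, r.interval.end,
                                     (r.metric, r.population, r.ranked_p))
    matches: list[SelectionMatch] = []
    for rec in records:
        hits = sorted(iv.data for iv in trees.get(rec.chrom, IntervalTree()).at(rec.position))
        matches.append(SelectionMatch(rec.indel.key, [h for h in hits if h[2] < 0.05]))
    n95 = sum(m.confidence_class in (C95, C99) for m in matches)
    n99 = sum(m.confidence_class == C99 for m in matches)
    return matches, MatchSummary(len(records), n95, n99)


@dataclass
class SweepProfile:
    """Sliding-window heterozygosity around a focal indel, by genotype class.

    ``het_present`` is averaged over samples homozygous for the indel
    (dosage 2), ``het_absent`` over samples homozygous for its absence
    (dosage 0).  Windows holding no variants are NaN.
    """

    focal_variant: str
    focal_position: int
    window_centers: np.ndarray
    het_present: np.ndarray
    het_absent: np.ndarray
    n_variants_per_window: np.ndarray


def _class_het(dos: np.ndarray, mode: str) -> np.ndarray:
    """Per-variant heterozygosity within one genotype class (rows = variants)."""
    called = dos != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "expected":
            p = np.where(called, dos, 0).sum(axis=1) / (2.0 * n)
            h = 2.0 * p * (1.0 - p)
        elif mode == "observed":
            h = np.where(called, dos == 1, False).sum(axis=1) / n
        else:
            raise ValueError(f"unknown heterozygosity mode {mode!r}")
    return np.where(n > 0, h, np.nan)


def sweep_profile(
    focal: IndelVariant,
    genotypes: GenotypeMatrix,
    span: int = 100_000,
    window: int = 5_000,
    step: int = 1_000,
    het: str = "expected",
    begin_rule: str = "first-changed",
) -> SweepProfile:
    """Genotype-stratified heterozygosity curve across ``span`` bp around the indel.

    For each sliding window of ``window`` bp (advanced by ``step``) the mean
    per-variant heterozygosity is computed separately in the two homozygote
    classes of the focal variant; the focal variant itself is excluded.
    Requires at least 2 samples per class and 1 variant in the span.
    """
    fi = genotypes.variant_index(focal.key)
    focal_dos = genotypes.dosage[fi]
    present = focal_dos == 2
    absent = focal_dos == 0
    for name, mask in (("homozygous-present", present), ("homozygous-absent", absent)):
        if mask.sum() < 2:
            raise ValueError(
                f"genotype class {name!r} has {int(mask.sum())} samples (need >= 2)"
            )
    b = focal.first_affected_base(begin_rule)
    positions = np.array([
        v.first_affected_base(begin_rule) if v.chrom == focal.chrom else -1
        for v in genotypes.variants
    ])
    in_span = (
        (positions >= b - span // 2) & (positions <= b + span // 2)
        & (np.arange(len(positions)) != fi) & (positions >= 0)
    )
    if not in_span.any():
        raise ValueError("no variants within the span around the focal indel")
    pos = positions[in_span]
    het_p = _class_het(genotypes.dosage[np.ix_(in_span, present)], het)
    het_a = _class_het(genotypes.dosage[np.ix_(in_span, absent)], het)
    centers = np.arange(b - span // 2, b + span // 2 + 1, step)
    mean_p = np.full(centers.shape, np.nan)
    mean_a = np.full(centers.shape, np.nan)
    counts = np.zeros(centers.shape, dtype=int)
    for i, c in enumerate(centers):
        sel = (pos >= c - window // 2) & (pos < c + window // 2)
        counts[i] = int(sel.sum())
        if counts[i]:
            mean_p[i] = np.nanmean(het_p[sel])
            mean_a[i] = np.nanmean(het_a[sel])
    return SweepProfile(focal.key, b, centers, mean_p, mean_a, counts)
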