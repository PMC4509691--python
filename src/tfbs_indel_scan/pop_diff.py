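"""Population differentiation via the minimum allele-frequency difference δ.

For variant i and target population j,

    δ(i, j) = min over k ≠ j of |f_ij − f_ik|

where f are derived-allele frequencies (derived = alternate allele unless an
ancestral annotation flips a variant; δ itself is orientation-invariant).
A variant is called highly differentiated in population j when δ(i, j)
reaches a threshold — either the fixed 0.2 convention or mean + 2 SD of the
pooled δ distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GenotypeMatrix


@dataclass
class FreqTable:
    """Per-(variant, population) derived-allele frequencies.

    ``freq`` is NaN where a population has zero called chromosomes at a
    variant; such pairs are excluded from δ rather than treated as zero.
    """

    variant_keys: list[str]
    populations: list[str]
    freq: np.ndarray      # (n_variants, n_populations), NaN = missing
    n_chrom: np.ndarray   # called chromosome counts, same shape

    def variant_row(self, key: str) -> int:
        return self.variant_keys.index(key)

    def frequency(self, variant: str, population: str) -> float:
        return float(self.freq[self.variant_row(variant),
                               self.populations.index(population)])


@dataclass(frozen=True)
class DeltaRecord:
    variant: str
    population: str
    delta: float
    nearest_population: str  # the k attaining the minimum (ties: lexicographic)
    direction: int           # sign of f_ij - f_ik for that k

    @property
    def signed_delta(self) -> float:
        return self.direction * self.delta


def compute_frequencies(
    genotypes: GenotypeMatrix,
    populations: list[str] | None = None,
    flip_derived: set[str] | None = None,
) -> FreqTable:
    """Derived-allele frequency per population: Σ dosages / (2 × called samples).

    Samples labelled 'unassigned' (e.g. admixed cohorts excluded from the
    differentiation analysis) never contribute.  ``flip_derived`` lists
    variant keys whose ancestral allele is the alternate, so their derived
    frequency is 1 − alternate frequency.
    """
    pops = populations if populations is not None else genotypes.populations
    if len(pops) < 1:
        raise ValueError("no assigned populations in the genotype matrix")
    n_v = genotypes.n_variants
    freq = np.full((n_v, len(pops)), np.nan)
    n_chrom = np.zeros((n_v, len(pops)), dtype=int)
    flip = flip_derived or set()
    for j, pop in enumerate(pops):
        idx = genotypes.sample_indices(pop)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has no samples")
        dos = genotypes.dosage[:, idx]
        called = dos != MISSING
        n = 2 * called.sum(axis=1)
        n_chrom[:, j] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called, dos, 0).sum(axis=1) / n
        freq[:, j] = np.where(n > 0, f, np.nan)
    for i, v in enumerate(genotypes.variants):
        if v.key in flip:
            freq[i] = 1.0 - freq[i]
    return FreqTable([v.key for v in genotypes.variants], list(pops), freq, n_chrom)


def delta(freqs: FreqTable, variant: str, population: str) -> DeltaRecord:
    """Evaluate δ for one (variant, population) pair.

    Raises if the target frequency is missing or no other population has a
    called frequency (δ undefined with a single population).
    """
    i = freqs.variant_row(variant)
    j = freqs.populations.index(population)
    f_j = freqs.freq[i, j]
    if np.isnan(f_j):
        raise ValueError(f"no called frequency for {variant} in {population}")
    best: tuple[float, str] | None = None
    for k, other in sorted(enumerate(freqs.populations), key=lambda t: t[1]):
        if k == j or np.isnan(freqs.freq[i, k]):
            continue
        diff = abs(f_j - freqs.freq[i, k])
        if best is None or diff < best[0]:
            best = (diff, other)
    if best is None:
        raise ValueError(
            f"delta undefined for {variant}: no other population with called frequency"
        )
    d, nearest = best
    f_k = freqs.freq[i, freqs.populations.index(nearest)]
    return DeltaRecord(variant, population, float(d), nearest,
                       int(np.sign(f_j - f_k)))


def delta_all(freqs: FreqTable) -> list[DeltaRecord]:
    """δ for every (variant, population) pair that admits one."""
    out = []
    for v in freqs.variant_keys:
        for p in freqs.populations:
            try:
                out.append(delta(freqs, v, p))
            except ValueError:
                continue
    return out


def delta_threshold(deltas: list[float] | list[DeltaRecord]) -> float:
    """mean + 2 × SD (population SD) of the pooled δ distribution.

    The fixed δ ≥ 0.2 convention approximates this on genome-wide data;
    callers may use either.
    """
    values = np.array([d.delta if isinstance(d, DeltaRecord) else d for d in deltas],
                      dtype=float)
    if values.size == 0:
        raise ValueError("cannot derive a threshold from an empty delta set")
    return float(values.mean() + 2.0 * values.std(ddof=0))


def select_differentiated(
    records: list[DeltaRecord], threshold: float = 0.2
) -> dict[str, list[DeltaRecord]]:
    """Partition records with δ ≥ threshold (boundary inclusive) by population."""
    out: dict[str, list[DeltaRecord]] = {}
    for rec in records:
        if rec.delta >= threshold:
            out.setdefault(rec.population, []).append(rec)
    return out
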