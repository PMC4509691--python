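"""Genotype-dosage versus expression association (eQTL-style Spearman test).

Samples are compared by indel genotype — 0 for reference homozygotes, 1 for
heterozygotes, 2 for alternate homozygotes — against FPKM expression of the
gene whose TSS window holds the TFBS-ID.  Ranks use mean-rank ties; with
ties the coefficient is the product-moment correlation of the rank vectors,
which reduces to the classical 1 − 6Σd²/(n³−n) formula when ranks are
unique.  P-values use the t approximation on n − 2 degrees of freedom,
two-sided; discovery is controlled by Benjamini–Hochberg at q ≤ 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import MISSING, ExpressionMatrix, GenotypeMatrix
from .tfbs_overlap import TfbsIdRecord


class NonInformativeError(ValueError):
    """Constant dosage/expression or too few paired samples to test."""


def _paired(dosages: np.ndarray, fpkm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dosages = np.asarray(dosages, dtype=float)
    fpkm = np.asarray(fpkm, dtype=float)
    if dosages.shape != fpkm.shape:
        raise ValueError("dosage and expression vectors differ in length")
    keep = (dosages != MISSING) & ~np.isnan(dosages) & ~np.isnan(fpkm)
    return dosages[keep], fpkm[keep]


def spearman(dosages: np.ndarray, fpkm: np.ndarray) -> tuple[float, float]:
    """Spearman r_s and two-sided p for paired dosage/expression vectors.

    Pairwise-missing entries are dropped first.  Raises NonInformativeError
    when fewer than 3 pairs remain or either vector is constant.  |r_s| = 1
    yields p = 0 by convention.
    """
    x, y = _paired(dosages, fpkm)
    n = x.size
    if n < 3:
        raise NonInformativeError(f"only {n} informative pairs (need >= 3)")
    if np.unique(x).size < 2:
        raise NonInformativeError("non-variable genotype")
    if np.unique(y).size < 2:
        raise NonInformativeError("non-quantified (constant) expression")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:  # all-tied ranks slip past the distinct-value check only if n tiny
        raise NonInformativeError("zero rank variance")
    r_s = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    if abs(r_s) == 1.0:
        return r_s, 0.0
    t = r_s * np.sqrt((n - 2) / (1.0 - r_s * r_s))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r_s, p


def spearman_d2(dosages: np.ndarray, fpkm: np.ndarray) -> float:
    """The rank-difference shortcut r_s = 1 − 6Σd²/(n³−n).

    Exact only when ranks are unique; kept as the tie-free special case of
    :func:`spearman`.
    """
    x, y = _paired(dosages, fpkm)
    n = x.size
    if n < 3:
        raise NonInformativeError(f"only {n} informative pairs (need >= 3)")
    d = stats.rankdata(x, method="average") - stats.rankdata(y, method="average")
    return float(1.0 - 6.0 * np.sum(d * d) / (n**3 - n))


def bh_correct(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class AssocResult:
    gene_id: str
    variant_id: str
    n: int
    r_s: float
    p_value: float
    q_value: float

    @property
    def direction(self) -> str | None:
        if self.r_s > 0:
            return "up"
        if self.r_s < 0:
            return "down"
        return None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.q_value <= alpha


@dataclass
class AssocSummary:
    """Gene-level tally of the association run.

    A gene is informative when at least one of its (gene, variant) pairs
    could be tested, significant when any pair reaches q ≤ alpha; it is
    counted 'up' if any significant pair has r_s > 0 and 'down' if any has
    r_s < 0 — a gene with mixed effects appears in both lists.
    """

    n_pairs_tested: int
    n_pairs_noninformative: int
    n_informative_genes: int
    n_significant_genes: int
    n_up_genes: int
    n_down_genes: int
    alpha: float = 0.05

    @property
    def significant_fraction(self) -> float:
        if self.n_informative_genes == 0:
            return 0.0
        return self.n_significant_genes / self.n_informative_genes


def run_association(
    records: list[TfbsIdRecord],
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    alpha: float = 0.05,
) -> tuple[list[AssocResult], AssocSummary]:
    """One Spearman test per (gene, TFBS-ID) pair over the sample intersection.

    BH correction is applied once across all performed tests.  Raises when
    genotype and expression cohorts share no samples.
    """
    expr_col = {s: i for i, s in enumerate(expression.samples)}
    geno_idx, fpkm_idx = [], []
    for i, s in enumerate(genotypes.samples):
        if s in expr_col:
            geno_idx.append(i)
            fpkm_idx.append(expr_col[s])
    if not geno_idx:
        raise ValueError("no overlapping samples between genotypes and expression")
    geno_idx = np.array(geno_idx)
    fpkm_idx = np.array(fpkm_idx)
    variant_row = {v.key: i for i, v in enumerate(genotypes.variants)}
    gene_row = {g: i for i, g in enumerate(expression.genes)}

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        for gene, _wc, _d in rec.gene_assignments:
            pair = (gene.gene_id, rec.indel.key)
            if pair not in seen and gene.gene_id in gene_row:
                seen.add(pair)
                pairs.append(pair)

    tested: list[tuple[str, str, int, float, float]] = []
    n_noninf = 0
    noninf_genes: set[str] = set()
    for gene_id, vkey in pairs:
        dos = genotypes.dosage[variant_row[vkey], geno_idx].astype(float)
        dos[dos == MISSING] = np.nan
        fpkm = expression.fpkm[gene_row[gene_id], fpkm_idx]
        try:
            r_s, p = spearman(dos, fpkm)
        except NonInformativeError:
            n_noninf += 1
            noninf_genes.add(gene_id)
            continue
        n = int(np.sum(~np.isnan(dos) & ~np.isnan(fpkm)))
        tested.append((gene_id, vkey, n, r_s, p))

    q = bh_correct([t[4] for t in tested])
    results = [
        AssocResult(g, v, n, r, p, float(qi))
        for (g, v, n, r, p), qi in zip(tested, q)
    ]
    informative = {r.gene_id for r in results}
    sig = [r for r in results if r.significant(alpha)]
    up = {r.gene_id for r in sig if r.r_s > 0}
    down = {r.gene_id for r in sig if r.r_s < 0}
    summary = AssocSummary(
        n_pairs_tested=len(results),
        n_pairs_noninformative=n_noninf,
        n_informative_genes=len(informative),
        n_significant_genes=len({r.gene_id for r in sig}),
        n_up_genes=len(up),
        n_down_genes=len(down),
        alpha=alpha,
    )
    return results, summary
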