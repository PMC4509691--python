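"""Label enrichment of an item subset against a universe.

Two nulls are provided.  The Monte Carlo null redraws random subsets of the
same size from the universe (without replacement) and asks how often a
label's simulated count reaches the observed count; the reported
p_mc = (1 + hits) / (n_sims + 1) never returns 0, so the resolution floor
at 10,000 simulations is just under 10^-4.  The hypergeometric null gives
the exact upper tail P(X >= observed) for items carrying a single label and
is used both for category enrichment and as the analytic cross-check of the
Monte Carlo estimate.

Items are opaque hashables: peaks labelled by their TF for factor-level
enrichment, gene IDs labelled by GMT categories for ontology-style
enrichment (an item may carry several labels).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Collection, Hashable, Iterable

import numpy as np
from scipy import stats

from .expr_assoc import bh_correct

LabelFn = Callable[[Hashable], Iterable[str]]


@dataclass(frozen=True)
class EnrichResult:
    label: str
    observed_count: int
    universe_size: int
    subset_size: int
    label_total_in_universe: int
    p_mc: float | None
    p_hyper: float | None
    q_value: float
    n_sims: int


def _prepare(subset: Collection, universe: Collection, label_of: LabelFn):
    universe_items = sorted(universe, key=repr)
    uset = set(universe_items)
    sset = set(subset)
    if not sset:
        raise ValueError("subset is empty")
    if not sset <= uset:
        raise ValueError("subset is not contained in the universe")
    labels = sorted({lab for item in universe_items for lab in label_of(item)})
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    member = np.zeros((len(universe_items), len(labels)), dtype=np.int32)
    for i, item in enumerate(universe_items):
        for lab in label_of(item):
            member[i, lab_idx[lab]] = 1
    in_subset = np.array([item in sset for item in universe_items])
    observed = member[in_subset].sum(axis=0)
    return universe_items, labels, member, observed, len(sset)


def mc_enrichment(
    subset: Collection,
    universe: Collection,
    label_of: LabelFn,
    n_sims: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EnrichResult]:
    """Monte Carlo enrichment p per label, BH-corrected across labels.

    Each simulation draws |subset| items uniformly without replacement from
    the universe; p_mc = (1 + #{simulated count >= observed}) / (n_sims + 1).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    items, labels, member, observed, k = _prepare(subset, universe, label_of)
    hits = np.zeros(len(labels), dtype=np.int64)
    n_items = len(items)
    for _ in range(n_sims):
        draw = rng.choice(n_items, size=k, replace=False)
        hits += member[draw].sum(axis=0) >= observed
    p_mc = (1.0 + hits) / (n_sims + 1.0)
    q = bh_correct(p_mc)
    totals = member.sum(axis=0)
    results = [
        EnrichResult(lab, int(observed[i]), n_items, k, int(totals[i]),
                     float(p_mc[i]), None, float(q[i]), n_sims)
        for i, lab in enumerate(labels)
    ]
    results.sort(key=lambda r: (r.p_mc, r.label))
    return results


def hypergeom_enrichment(
    subset: Collection,
    universe: Collection,
    label_of: LabelFn,
) -> list[EnrichResult]:
    """Exact upper-tail hypergeometric enrichment p per label, BH-corrected.

    P(X >= observed) with population = universe size, successes = items
    carrying the label, draws = subset size.
    """
    items, labels, member, observed, k = _prepare(subset, universe, label_of)
    totals = member.sum(axis=0)
    n_items = len(items)
    p = np.array([
        float(stats.hypergeom.sf(observed[i] - 1, n_items, int(totals[i]), k))
        for i in range(len(labels))
    ])
    p = np.clip(p, 0.0, 1.0)
    q = bh_correct(p)
    results = [
        EnrichResult(lab, int(observed[i]), n_items, k, int(totals[i]),
                     None, float(p[i]), float(q[i]), 0)
        for i, lab in enumerate(labels)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.label))
    return results
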