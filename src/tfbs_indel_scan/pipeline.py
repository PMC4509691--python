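"""End-to-end orchestration: overlap → window annotation → δ → association →
enrichment → selection matching, with a JSON manifest of stage counts."""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import data_io, enrichment, expr_assoc, pop_diff, selection_scan, tfbs_overlap
from .tfbs_overlap import WINDOW_FLANKING, WINDOW_UPSTREAM

logger = logging.getLogger("tfbs_indel_scan")


class StageError(RuntimeError):
    """A pipeline stage failed; completed intermediates stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    peaks: str
    vcf: str
    sample_map: str
    genes: str
    out_dir: str
    expression: str | None = None
    gmt: str | None = None
    track: str | None = None
    windows: tuple[str, ...] = (WINDOW_UPSTREAM,)
    max_indel_len: int = 200
    delta_mode: str = "fixed"        # fixed | mean2sd
    delta_threshold: float = 0.2
    alpha: float = 0.05
    n_sims: int = 10000
    seed: int = 0
    begin_rule: str = "first-changed"

    def __post_init__(self) -> None:
        for w in self.windows:
            if w not in (WINDOW_UPSTREAM, WINDOW_FLANKING):
                raise ValueError(f"unknown window {w!r}")
        if self.delta_mode not in ("fixed", "mean2sd"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        for name in ("peaks", "vcf", "sample_map", "genes"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "windows" in raw:
            raw["windows"] = tuple(raw["windows"])
        return cls(**raw)


# --------------------------------------------------------------------------
# intermediate writers
# --------------------------------------------------------------------------

def _write_records_tsv(records, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tchrom\tposition\ttype\tlength\ttf_name\t"
                 "peak_start\tpeak_end\tgene_id\twindow\tdistance_to_tss\n")
        for r in records:
            assignments = r.gene_assignments or [(None, ".", ".")]
            for p in r.affected_peaks:
                for g, wc, d in assignments:
                    gid = g.gene_id if g else "."
                    fh.write(f"{r.indel.key}\t{r.chrom}\t{r.position}\t"
                             f"{r.indel.indel_type}\t{r.indel.length}\t{p.tf_name}\t"
                             f"{p.interval.start}\t{p.interval.end}\t{gid}\t{wc}\t{d}\n")


def _write_delta_tsv(selected: dict, freqs, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tpopulation\tfrequency\tsigned_delta\tnearest_population\n")
        for pop in sorted(selected):
            for rec in selected[pop]:
                f = freqs.frequency(rec.variant, rec.population)
                fh.write(f"{rec.variant}\t{rec.population}\t{f:.6g}\t"
                         f"{rec.signed_delta:+.2f}\t{rec.nearest_population}\n")


def _write_assoc_tsv(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvariant_id\tn\tr_s\tp_value\tq_value\tdirection\n")
        for r in results:
            fh.write(f"{r.gene_id}\t{r.variant_id}\t{r.n}\t{r.r_s:.6g}\t"
                     f"{r.p_value:.6g}\t{r.q_value:.6g}\t{r.direction or '.'}\n")


def _write_enrich_tsv(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tobserved\tsubset_size\tlabel_total\tuniverse_size\t"
                 "p_mc\tp_hyper\tq_value\n")
        for r in results:
            pmc = f"{r.p_mc:.6g}" if r.p_mc is not None else "."
            ph = f"{r.p_hyper:.6g}" if r.p_hyper is not None else "."
            fh.write(f"{r.label}\t{r.observed_count}\t{r.subset_size}\t"
                     f"{r.label_total_in_universe}\t{r.universe_size}\t{pmc}\t{ph}\t"
                     f"{r.q_value:.6g}\n")


def _write_selection_tsv(matches, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tconfidence_class\tmin_ranked_p\tn_matched\n")
        for m in matches:
            mp = f"{m.min_ranked_p:.6g}" if m.min_ranked_p is not None else "."
            fh.write(f"{m.variant_id}\t{m.confidence_class}\t{mp}\t{len(m.matched)}\n")


def peaks_near_genes(peaks, genes, windows) -> list:
    """Peaks with at least one base inside a TSS window of some gene."""
    near = []
    for p in peaks:
        hit = False
        for g in genes:
            if g.interval.chrom != p.interval.chrom:
                continue
            for w in windows:
                d0 = tfbs_overlap.signed_tss_distance(p.interval.start, g)
                d1 = tfbs_overlap.signed_tss_distance(p.interval.end - 1, g)
                lo, hi = min(d0, d1), max(d0, d1)
                # the window is an interval in distance space; the peak spans [lo, hi]
                if any(tfbs_overlap.in_window(d, w) for d in range(lo, hi + 1)):
                    hit = True
                    break
            if hit:
                break
        if hit:
            near.append(p)
    return near


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing each intermediate as it completes.

    Returns the manifest (also written to out_dir/manifest.json).  A stage
    failure raises StageError naming the stage; outputs of completed stages
    persist in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    cfg["windows"] = list(config.windows)
    manifest: dict = {"seed": config.seed, "config": cfg}
    state: dict = {}

    stages = [("load", _stage_load), ("overlap", _stage_overlap),
              ("popdiff", _stage_popdiff)]
    if config.expression:
        stages.append(("association", _stage_association))
    stages.append(("enrichment_tf", _stage_tf_enrichment))
    if config.gmt:
        stages.append(("enrichment_categories", _stage_category_enrichment))
    if config.track:
        stages.append(("selection", _stage_selection))

    for name, fn in stages:
        logger.info("pipeline stage: %s", name)
        try:
            fn(config, state, manifest, out)
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            _dump_manifest(manifest, out)
            raise StageError(name, exc) from exc
    _dump_manifest(manifest, out)
    return manifest


def _stage_load(config, state, manifest, out) -> None:
    state["peaks"] = data_io.read_peaks(config.peaks)
    state["genotypes"] = data_io.read_indel_genotypes(config.vcf, config.sample_map)
    state["genes"] = data_io.read_genes(config.genes)
    manifest["n_peaks"] = len(state["peaks"])
    manifest["n_indels_read"] = state["genotypes"].n_variants
    manifest["n_genes"] = len(state["genes"])


def _stage_overlap(config, state, manifest, out) -> None:
    records = tfbs_overlap.find_tfbs_id(
        state["peaks"], state["genotypes"], config.max_indel_len, config.begin_rule)
    for w in config.windows:
        tfbs_overlap.assign_genes(records, state["genes"], w)
    summary = tfbs_overlap.summarize(records)
    (out / "overlap_summary.json").write_text(json.dumps({
        "n_tfbs_affected": summary.n_tfbs_affected,
        "n_unique_indels": summary.n_unique_indels,
        "mean_tfbs_per_indel": summary.mean_tfbs_per_indel,
        "per_tf_counts": summary.per_tf_counts,
        "position_histogram": summary.position_histogram,
    }, sort_keys=True, indent=1))
    _write_records_tsv(records, out / "tfbs_id.tsv")
    manifest["n_tfbs_id"] = summary.n_unique_indels
    manifest["n_tfbs_affected"] = summary.n_tfbs_affected
    manifest["n_gene_assignments"] = sum(len(r.gene_assignments) for r in records)
    manifest["n_genes_with_tfbs_id"] = len(
        {g.gene_id for r in records for g, _, _ in r.gene_assignments})
    state["records"] = records


def _stage_popdiff(config, state, manifest, out) -> None:
    freqs = pop_diff.compute_frequencies(state["genotypes"])
    keys = {r.indel.key for r in state["records"]}
    deltas = [d for d in pop_diff.delta_all(freqs) if d.variant in keys]
    if config.delta_mode == "mean2sd" and deltas:
        threshold = pop_diff.delta_threshold(deltas)
    else:
        threshold = config.delta_threshold
    selected = pop_diff.select_differentiated(deltas, threshold)
    _write_delta_tsv(selected, freqs, out / "differentiated.tsv")
    manifest["delta_threshold"] = threshold
    manifest["n_differentiated_per_population"] = {
        p: len(v) for p, v in sorted(selected.items())}
    state["freqs"] = freqs
    state["deltas"] = deltas


def _stage_association(config, state, manifest, out) -> None:
    expression = data_io.read_expression(config.expression)
    results, summary = expr_assoc.run_association(
        state["records"], state["genotypes"], expression, config.alpha)
    _write_assoc_tsv(results, out / "association.tsv")
    (out / "association_summary.json").write_text(json.dumps({
        "n_pairs_tested": summary.n_pairs_tested,
        "n_pairs_noninformative": summary.n_pairs_noninformative,
        "n_informative_genes": summary.n_informative_genes,
        "n_significant_genes": summary.n_significant_genes,
        "n_up_genes": summary.n_up_genes,
        "n_down_genes": summary.n_down_genes,
        "significant_fraction": summary.significant_fraction,
    }, sort_keys=True, indent=1))
    manifest["association"] = {
        "informative_genes": summary.n_informative_genes,
        "significant_genes": summary.n_significant_genes,
        "up": summary.n_up_genes, "down": summary.n_down_genes,
    }


def _stage_tf_enrichment(config, state, manifest, out) -> None:
    near = sorted(set(peaks_near_genes(state["peaks"], state["genes"], config.windows)))
    near_set = set(near)
    affected = sorted({p for r in state["records"] for p in r.affected_peaks
                       if p in near_set})
    if affected:
        results = enrichment.mc_enrichment(
            affected, near, lambda p: [p.tf_name],
            n_sims=config.n_sims, seed=config.seed)
        _write_enrich_tsv(results, out / "enrichment_tf.tsv")
        manifest["n_tf_labels_tested"] = len(results)
    else:
        manifest["n_tf_labels_tested"] = 0


def _stage_category_enrichment(config, state, manifest, out) -> None:
    categories = data_io.read_gmt(config.gmt)

    def labels_of(gene_id):
        return [c for c, members in categories.items() if gene_id in members]

    universe = sorted({g.gene_id for g in state["genes"]})
    subset = sorted({g.gene_id for r in state["records"]
                     for g, _, _ in r.gene_assignments})
    if not subset:
        manifest["n_categories_tested"] = 0
        return
    hyper = enrichment.hypergeom_enrichment(subset, universe, labels_of)
    mc = enrichment.mc_enrichment(subset, universe, labels_of,
                                  n_sims=config.n_sims, seed=config.seed)
    p_mc_of = {r.label: r.p_mc for r in mc}
    merged = [
        enrichment.EnrichResult(
            r.label, r.observed_count, r.universe_size, r.subset_size,
            r.label_total_in_universe, p_mc_of.get(r.label),
            r.p_hyper, r.q_value, config.n_sims)
        for r in hyper
    ]
    _write_enrich_tsv(merged, out / "enrichment_categories.tsv")
    manifest["n_categories_tested"] = len(merged)


def _stage_selection(config, state, manifest, out) -> None:
    track = data_io.read_selection_track(config.track)
    matches, summary = selection_scan.match_selection(state["records"], track)
    _write_selection_tsv(matches, out / "selection.tsv")
    manifest["selection"] = {
        "n_records": summary.n_records,
        "n_c95": summary.n_c95, "n_c99": summary.n_c99,
        "fraction_c95": summary.fraction_c95,
        "fraction_c99": summary.fraction_c99,
    }


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
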