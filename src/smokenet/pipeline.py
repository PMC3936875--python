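"""End-to-end orchestration of the analysis stages.

Stages communicate through files only; a run manifest records the seed,
per-stage record counts and output digests so identical configs give
byte-identical results. A single global seed fans out to per-stage
streams (each generator op derives its own substream), so toggling one
stage never shifts another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cellmix, enrichment, ewas, io, modules, promoter, simulate
from .stats import pearson_correlation

log = logging.getLogger("smokenet")


@dataclass
class PipelineConfig:
    outdir: str = "smokenet_run"
    seed: int = 0
    alpha_ewas: float = 0.05
    alpha_modules: float = 0.05
    promoter_categories: tuple = ("TSS1500", "TSS200")
    surrogate_top_k: int = 100
    surrogate_n_components: int = 5
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    panel: dict = field(default_factory=dict)    # ReferencePanelSpec overrides
    ppi: dict = field(default_factory=dict)      # generate_ppi overrides
    go: dict = field(default_factory=dict)       # generate_go_annotation overrides
    search: dict = field(default_factory=dict)   # SearchConfig overrides

    def __post_init__(self):
        for a in (self.alpha_ewas, self.alpha_modules):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run simulate -> cell composition -> EWAS -> promoter -> network ->
    module search -> GO enrichment, writing every intermediate to
    ``config.outdir`` and returning the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, float] = {}

    # --- simulate cohort and reference panel
    cspec = simulate.CohortSpec(seed=config.seed, **config.cohort)
    pspec = simulate.ReferencePanelSpec(seed=config.seed, n_probes=cspec.n_probes, **config.panel)
    betas, sheet, annotation, truth = simulate.generate_cohort(cspec, pspec)
    panel, labels, _ = simulate.generate_reference_panel(pspec)
    io.write_beta_matrix(betas, out / "cohort_betas.tsv")
    io.write_sample_sheet(sheet, out / "sample_sheet.tsv")
    io.write_probe_annotation(annotation, out / "probe_annotation.tsv")
    io.write_beta_matrix(panel, out / "panel_betas.tsv")
    labels.to_csv(out / "panel_labels.tsv", sep="\t", index_label="sample_id")
    counts["probes"] = len(betas.probe_ids)
    counts["samples"] = len(betas.sample_ids)

    # --- cell-mixture surrogates
    ranking = cellmix.derive_celltype_sites(panel, labels)
    ranking.table.to_csv(out / "celltype_sites.tsv", sep="\t", index_label="probe_id")
    surrogates = cellmix.compute_surrogates(
        betas, ranking, top_k=config.surrogate_top_k, n_components=config.surrogate_n_components
    )
    cellmix.write_surrogates(surrogates, out / "surrogates.tsv")
    counts["celltype_sites_significant"] = ranking.n_significant

    # --- probe-level EWAS
    results = ewas.fit_probe_models(betas, sheet, surrogates, annotation=annotation)
    io.write_ranked_table(results, out / "ewas_ranked.tsv")
    n_sig, _ = ewas.summarize_counts(results, config.alpha_ewas)
    counts["probes_fitted"] = results.attrs["m_total"]
    counts["probes_significant"] = n_sig

    # --- promoter-level tests and weighted network
    mapping = promoter.assign_promoter_probes(annotation, set(config.promoter_categories))
    gene_table = promoter.promoter_t_tests(betas, sheet, mapping)
    gene_table.to_csv(out / "gene_pvalues.tsv", sep="\t", index_label="gene_symbol")
    counts["genes_tested"] = len(gene_table)

    ppi_kwargs = dict(config.ppi)
    edges, ppi_truth = simulate.generate_ppi(gene_table["adjusted_p"], seed=config.seed, **ppi_kwargs)
    io.write_edge_list(edges, out / "ppi_edges.tsv")
    network = promoter.build_weighted_network(edges, gene_table)
    io.export_network(network, str(out / "weighted_network"))
    counts["edges_weighted"] = network.number_of_edges()

    # --- module discovery
    search = modules.SearchConfig(seed=config.seed, alpha=config.alpha_modules, **config.search)
    found = modules.find_modules(network, search)
    with open(out / "modules.tsv", "w") as fh:
        fh.write("module\tsize\tscore\tempirical_p\tmembers\n")
        for i, m in enumerate(found, 1):
            fh.write(f"M{i}\t{m.size}\t{m.score:.6g}\t{m.empirical_p:.6g}\t{','.join(sorted(m.members))}\n")
            io.export_network(network.subgraph(m.members), str(out / f"module_M{i}"))
    counts["modules_accepted"] = len(found)

    # --- GO enrichment: genome-wide mode and per-module mode
    go_kwargs = dict(config.go)
    planted = [(set(mod), go_kwargs.pop("odds_ratio", 20.0)) for mod in ppi_truth.modules]
    collection, _ = simulate.generate_go_annotation(
        list(gene_table.index), enriched=planted, seed=config.seed, **go_kwargs
    )
    io.write_gmt(collection, out / "go_annotation.gmt")
    changed = enrichment.changed_genes_from_ewas(results, annotation, alpha=config.alpha_ewas)
    counts["genes_changed"] = len(changed.changed)
    if changed.changed:
        table = enrichment.enrich(changed.changed, changed.universe, collection)
        enrichment.write_enrichment(table, out / "enrichment_genomewide.tsv")
    network_universe = set(network.nodes)
    for i, m in enumerate(found, 1):
        table = enrichment.enrich(m.members, network_universe, collection)
        enrichment.write_enrichment(table, out / f"enrichment_module_M{i}.tsv")

    # audit lines mirroring the scale of the original cohort analysis
    log.info("pipeline counts: %s", counts)
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "counts": counts,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"},
        "truth": {
            "effect_probes": len(truth.effect_probes),
            "planted_modules": [sorted(m) for m in ppi_truth.modules],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_concordance(x_path, y_path, out_path=None) -> float:
    """Pearson correlation between two aligned single-locus methylation
    vectors (e.g., array vs qPCR), with a paired-value TSV export.

    Each input is a two-column TSV: sample_id, methylation value.
    """
    x = pd.read_csv(x_path, sep="\t", index_col=0).iloc[:, 0]
    y = pd.read_csv(y_path, sep="\t", index_col=0).iloc[:, 0]
    if set(x.index) != set(y.index):
        mism = sorted(set(x.index) ^ set(y.index))[:10]
        raise ValueError(f"misaligned sample ids: {mism}")
    y = y.reindex(x.index)
    r = pearson_correlation(x.to_numpy(), y.to_numpy())
    if out_path is not None:
        pd.DataFrame({"x": x, "y": y}).to_csv(out_path, sep="\t", index_label="sample_id",
                                              float_format="%.6g")
    return r
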