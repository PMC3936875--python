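"""Hypergeometric GO over-representation analysis.

Two use-modes share one operation: genome-wide enrichment of the genes
carrying significant probes, and per-sub-network enrichment of module
members against the weighted-network universe. Correction is BH by
default; a permutation mode (resampled query sets of equal size)
approximates a resampling FDR.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd

from .io import GeneSetCollection, ProbeAnnotation
from .stats import bh_adjust, hypergeom_tail

ChangedGenes = namedtuple("ChangedGenes", ["changed", "universe"])


def enrich(
    query,
    universe,
    collection: GeneSetCollection,
    correction: str = "bh",
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each gene set.

    Each term is intersected with ``universe`` before testing (empty
    terms skipped); the raw p is the hypergeometric upper tail of the
    query/term overlap. Returns rows sorted ascending by raw p with
    columns term_id, term_name, total (term in universe), changed (term
    in query), raw_p, log10_raw_p, corrected_p.

    ``correction`` is ``"bh"`` (default) or ``"permutation"`` — the
    latter estimates, per term, an FDR-style q as the add-one fraction
    of equally-sized random queries achieving a raw p at least as small.
    """
    query = {g.upper() for g in query}
    universe = {g.upper() for g in universe}
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe: {extra}")
    rows = []
    for tid, (name, members) in sorted(collection.items()):
        in_universe = members & universe
        if not in_universe:
            continue
        changed = len(in_universe & query)
        raw = hypergeom_tail(changed, len(in_universe), len(query), len(universe))
        rows.append((tid, name, len(in_universe), changed, raw))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "total", "changed", "raw_p"])
    out["log10_raw_p"] = np.log10(out["raw_p"])
    if correction == "bh":
        out["corrected_p"] = bh_adjust(out["raw_p"].to_numpy())
    elif correction == "permutation":
        rng = np.random.default_rng([seed, 6])
        uni = sorted(universe)
        k = len(query)
        null_mins = np.ones((n_permutations, len(out)))
        term_sets = [collection.terms[t][1] & universe for t in out["term_id"]]
        for r in range(n_permutations):
            q = set(rng.choice(uni, size=k, replace=False))
            for j, members in enumerate(term_sets):
                null_mins[r, j] = hypergeom_tail(len(members & q), len(members), k, len(universe))
        exceed = (null_mins <= out["raw_p"].to_numpy()[None, :]).sum(axis=0)
        out["corrected_p"] = np.minimum((1 + exceed) / (1 + n_permutations), 1.0)
        out["corrected_p"] = np.maximum(out["corrected_p"], out["raw_p"])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out.sort_values(["raw_p", "term_id"], kind="stable").reset_index(drop=True)


def changed_genes_from_ewas(
    results: pd.DataFrame,
    annotation: ProbeAnnotation,
    alpha: float = 0.05,
) -> ChangedGenes:
    """Genes owning >= 1 significant probe, with the fitted-probe universe.

    ``results`` is the probe-level EWAS table; a gene is "changed" when
    at least one of its probes has BH-adjusted p <= alpha, and the
    universe is every gene owning at least one fitted probe.
    """
    genes_of = annotation.table["gene_symbols"]
    fitted = results["probe_id"]
    universe = {g for p in fitted for g in genes_of.get(p, ())}
    sig = results.loc[results["adjusted_p"] <= alpha, "probe_id"]
    changed = {g for p in sig for g in genes_of.get(p, ())}
    return ChangedGenes(changed, universe)


def write_enrichment(table: pd.DataFrame, path, sep="\t") -> None:
    table.to_csv(path, sep=sep, index=False, float_format="%.6g")
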