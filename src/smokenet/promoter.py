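"""Promoter-level differential methylation and the p-value-weighted network.

For each gene, all beta values of its promoter-category probes are
flattened into one vector per group (smokers, non-smokers) and compared
by an unpaired t-test; BH adjustment over genes yields the gene-level
adjusted p-values p'. A PPI edge list is then weighted by

    w_ij = log(p'_i * p'_j) / log(p'_min^2)

which maps gene-pair significance into [0, 1]: w = 1 when both genes sit
at the table minimum, w = 0 when both are at p' = 1. The logarithm base
cancels in the ratio.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import BetaMatrix, EdgeList, ProbeAnnotation, SampleSheet
from .stats import bh_adjust

log = logging.getLogger("smokenet")

PROMOTER_CATEGORIES = frozenset({"TSS1500", "TSS200"})
P_FLOOR = 1e-300


def assign_promoter_probes(
    annotation: ProbeAnnotation,
    promoter_categories=PROMOTER_CATEGORIES,
) -> dict[str, set]:
    """Map each gene to its promoter-category probe ids.

    A probe annotated to k genes appears in all k genes' sets; genes with
    no promoter-category probe are omitted.
    """
    mapping: dict[str, set] = {}
    placements = annotation.table["placement"].to_numpy()
    gene_lists = annotation.table["gene_symbols"].to_numpy()
    probes = annotation.probe_ids.to_numpy()
    for probe, genes, placement in zip(probes, gene_lists, placements):
        if placement in promoter_categories:
            for g in genes:
                mapping.setdefault(g, set()).add(probe)
    return mapping


def promoter_t_tests(
    betas: BetaMatrix,
    sheet: SampleSheet,
    mapping: dict[str, set],
    per_sample_mean: bool = False,
) -> pd.DataFrame:
    """Gene-level smoker vs non-smoker t-tests on flattened promoter vectors.

    The smoker vector of a gene is every unmasked (promoter probe x
    smoker sample) beta value; likewise for non-smokers. With
    ``per_sample_mean`` the probes are first averaged within sample,
    which changes the degrees of freedom materially. Genes with fewer
    than 2 values in either group are dropped and logged.

    Returns a DataFrame indexed by gene symbol with columns raw_p,
    adjusted_p, t_statistic, n_probes, n_smoker_values,
    n_nonsmoker_values.
    """
    smoker = sheet.smoker_flags(betas.sample_ids).astype(bool)
    v = betas.masked_values().to_numpy()
    probe_pos = {p: i for i, p in enumerate(betas.probe_ids)}

    # per-probe per-group sufficient statistics; gene-level flattened
    # moments are sums of probe-level ones
    valid = ~np.isnan(v)
    vv = np.where(valid, v, 0.0)
    stats = {}
    for flag, key in ((smoker, "s"), (~smoker, "n")):
        sub, subv = vv[:, flag], valid[:, flag]
        stats[key] = (subv.sum(axis=1), sub.sum(axis=1), (sub**2).sum(axis=1))
    if per_sample_mean:
        means = {}
        for flag, key in ((smoker, "s"), (~smoker, "n")):
            means[key] = (v[:, flag], valid[:, flag])

    genes, rows, dropped = [], [], 0
    for gene in sorted(mapping):
        idx = [probe_pos[p] for p in mapping[gene] if p in probe_pos]
        if not idx:
            dropped += 1
            continue
        idx = np.array(idx)
        if per_sample_mean:
            grp = []
            for key in ("s", "n"):
                sub, subv = means[key]
                with np.errstate(invalid="ignore"):
                    m = np.nansum(np.where(subv[idx], sub[idx], np.nan), axis=0) / subv[idx].sum(axis=0)
                grp.append(m[~np.isnan(m)])
            (n1, s1, q1) = (len(grp[0]), grp[0].sum(), (grp[0] ** 2).sum())
            (n2, s2, q2) = (len(grp[1]), grp[1].sum(), (grp[1] ** 2).sum())
        else:
            n1, s1, q1 = (stats["s"][0][idx].sum(), stats["s"][1][idx].sum(), stats["s"][2][idx].sum())
            n2, s2, q2 = (stats["n"][0][idx].sum(), stats["n"][1][idx].sum(), stats["n"][2][idx].sum())
        if n1 < 2 or n2 < 2:
            dropped += 1
            continue
        genes.append(gene)
        rows.append((n1, s1, q1, n2, s2, q2, len(idx)))
    if dropped:
        log.info("promoter_t_tests: %d genes dropped (insufficient values)", dropped)
    if not rows:
        raise ValueError("no gene had enough promoter values to test")

    arr = np.array(rows, dtype=float)
    n1, s1, q1, n2, s2, q2, n_probes = arr.T
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1**2
    ss2 = q2 - n2 * m2**2
    dof = n1 + n2 - 2
    pooled = (ss1 + ss2) / dof
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / se
    from scipy import stats as _sps
    raw_p = np.where(se > 0, 2.0 * _sps.t.sf(np.abs(np.nan_to_num(t)), dof), 1.0)
    t = np.where(se > 0, np.nan_to_num(t), 0.0)
    raw_p = np.clip(raw_p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(raw_p)
    return pd.DataFrame(
        {
            "raw_p": raw_p,
            "adjusted_p": adj,
            "t_statistic": t,
            "n_probes": n_probes.astype(int),
            "n_smoker_values": n1.astype(int),
            "n_nonsmoker_values": n2.astype(int),
        },
        index=pd.Index(genes, name="gene_symbol"),
    )


def edge_weight(p_i: float, p_j: float, p_min: float) -> float:
    """Significance-derived edge weight w = log(p_i*p_j) / log(p_min^2).

    Equals (log p_i + log p_j) / (2 log p_min): 1 when both genes sit at
    the table minimum, 0 when both are at p = 1, strictly decreasing in
    each p. p-values below 1e-300 are floored before taking logs.
    """
    if p_min >= 1.0:
        raise ValueError("unweightable network: minimum adjusted p is 1")
    for name, p in (("p_i", p_i), ("p_j", p_j), ("p_min", p_min)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} outside [0, 1]: {p}")
    p_i, p_j, p_min = (max(p, P_FLOOR) for p in (p_i, p_j, p_min))
    return (np.log(p_i) + np.log(p_j)) / (2.0 * np.log(p_min))


def build_weighted_network(edges: EdgeList, table: pd.DataFrame) -> nx.Graph:
    """Attach significance weights to a PPI edge list.

    ``table`` is the gene p'-table from :func:`promoter_t_tests`. Edges
    with an endpoint missing from the table are dropped (count logged).
    Nodes carry ``adjusted_p`` and ``neg_log10_p`` attributes; edges
    carry ``weight``.
    """
    pprime = table["adjusted_p"]
    p_min = float(pprime.min())
    if p_min >= 1.0:
        raise ValueError("unweightable network: all gene adjusted p-values are 1")
    known = set(pprime.index)
    g = nx.Graph(log_p_min=float(np.log(max(p_min, P_FLOOR))))
    dropped = 0
    log_p = np.log(np.maximum(pprime.to_numpy(), P_FLOOR))
    lp = dict(zip(pprime.index, log_p))
    denom = 2.0 * np.log(max(p_min, P_FLOOR))
    for a, b in edges.edges:
        if a in known and b in known:
            g.add_edge(a, b, weight=(lp[a] + lp[b]) / denom)
        else:
            dropped += 1
    if g.number_of_edges() == 0:
        raise ValueError("no edge endpoints map to the gene p-value table")
    if dropped:
        log.info("build_weighted_network: %d edges dropped (unmapped endpoints); %d kept",
                 dropped, g.number_of_edges())
    for n in g.nodes:
        p = float(pprime[n])
        g.nodes[n]["adjusted_p"] = p
        g.nodes[n]["neg_log10_p"] = float(-np.log10(max(p, P_FLOOR)))
    return g
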