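"""Cell-mixture surrogate covariates.

Blood methylation is confounded by cell-type composition. Following the
regression-calibration idea, probes that separate purified cell types in
a reference panel are ranked by a one-way F-test; the cohort's betas at
the top-ranked sites are then summarized by PCA, and the leading
component scores serve as per-sample surrogate covariates in the EWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import BetaMatrix
from .stats import bh_adjust

log = logging.getLogger("smokenet")


@dataclass
class CellTypeSiteRanking:
    """Per-probe cell-type F-test results, sorted ascending by raw p."""

    table: pd.DataFrame  # index probe_id; columns raw_p, adjusted_p, rank
    n_significant: int
    alpha: float


@dataclass
class SurrogateScores:
    """Leading PCA scores of cohort betas at cell-type-informative sites."""

    scores: pd.DataFrame            # samples x components (PC1..PCk)
    explained_variance: np.ndarray  # fraction per component, non-increasing


def derive_celltype_sites(panel: BetaMatrix, labels: pd.Series, alpha: float = 0.05) -> CellTypeSiteRanking:
    """Rank probes by differential methylation across purified cell types.

    Per probe, a one-way fixed-effects model of beta on cell-type
    indicators is scored by its overall F-test; p-values are BH-adjusted
    over all probes tested. ``labels`` maps panel sample id to cell type;
    every type needs at least 2 replicates.
    """
    labels = labels.reindex(panel.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some panel samples")
    groups = labels.groupby(labels).size()
    if len(groups) < 2:
        raise ValueError("need at least 2 cell types")
    if (groups < 2).any():
        bad = list(groups.index[groups < 2])
        raise ValueError(f"cell types with < 2 replicates: {bad}")

    v = panel.masked_values().to_numpy()
    type_codes, uniq = pd.factorize(labels)
    k = len(uniq)
    n_obs = np.zeros(v.shape[0])
    # vectorized one-way ANOVA with per-probe complete cases
    valid = ~np.isnan(v)
    vv = np.where(valid, v, 0.0)
    grand_sum = vv.sum(axis=1)
    n_obs = valid.sum(axis=1)
    ssb = np.zeros(v.shape[0])
    ssw = np.zeros(v.shape[0])
    df_b = np.zeros(v.shape[0])
    group_sums = np.zeros((v.shape[0], k))
    group_ns = np.zeros((v.shape[0], k))
    for g in range(k):
        cols = type_codes == g
        group_sums[:, g] = vv[:, cols].sum(axis=1)
        group_ns[:, g] = valid[:, cols].sum(axis=1)
    grand_mean = grand_sum / np.maximum(n_obs, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        group_means = group_sums / group_ns
    sst = (np.where(valid, (v - grand_mean[:, None]) ** 2, 0.0)).sum(axis=1)
    ssb = np.nansum(group_ns * (group_means - grand_mean[:, None]) ** 2, axis=1)
    ssw = sst - ssb
    k_eff = (group_ns >= 1).sum(axis=1)
    df1 = np.maximum(k_eff - 1, 1)
    df2 = np.maximum(n_obs - k_eff, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / df1) / (ssw / df2)
    raw_p = np.where(ssw <= 1e-300, np.where(ssb <= 1e-300, 1.0, 1e-300), _sps.f.sf(f, df1, df2))
    raw_p = np.clip(np.nan_to_num(raw_p, nan=1.0), 0.0, 1.0)

    adj = bh_adjust(raw_p)
    tab = pd.DataFrame({"raw_p": raw_p, "adjusted_p": adj}, index=panel.probe_ids)
    tab = tab.sort_values("raw_p", kind="stable")
    tab["rank"] = np.arange(1, len(tab) + 1)
    n_sig = int((tab["adjusted_p"] <= alpha).sum())
    log.info("derive_celltype_sites: %d/%d sites significant at BH %.2g", n_sig, len(tab), alpha)
    return CellTypeSiteRanking(tab, n_sig, alpha)


def compute_surrogates(
    cohort: BetaMatrix,
    ranking: CellTypeSiteRanking,
    top_k: int = 100,
    n_components: int = 5,
) -> SurrogateScores:
    """PCA surrogate scores of cohort betas at the top-ranked reference sites.

    PCA is run on the cohort's samples x top-``top_k``-sites matrix
    (column mean-centered, unscaled — all features share the beta
    scale); the first ``n_components`` sample scores are returned with
    explained-variance fractions. A tie in raw p at the ``top_k``
    boundary includes all tied sites. Signs are fixed so that each
    component's largest-magnitude loading is positive.
    """
    tab = ranking.table
    if top_k < len(tab):
        cut = tab["raw_p"].iloc[top_k - 1]
        sel = tab.index[(tab["raw_p"] <= cut)]
        if len(sel) > top_k:
            log.warning("compute_surrogates: tie at top-%d boundary, using %d sites", top_k, len(sel))
    else:
        sel = tab.index
    present = sel.intersection(cohort.probe_ids)
    if len(present) < len(sel):
        log.warning("compute_surrogates: only %d/%d selected sites present in cohort", len(present), len(sel))
    if len(present) < n_components:
        raise ValueError(f"only {len(present)} selected sites available; need >= {n_components}")
    if len(cohort.sample_ids) < n_components + 1:
        raise ValueError("need more cohort samples than components")

    x = cohort.masked_values().loc[present].to_numpy().T  # samples x sites
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x = x - x.mean(axis=0)
    if not np.any(x):
        raise ValueError("degenerate input: all samples identical at the selected sites")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    evr = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):  # deterministic sign convention
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1.0
    out = pd.DataFrame(
        scores,
        index=cohort.sample_ids,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return SurrogateScores(out, evr[:n_components])


def write_surrogates(s: SurrogateScores, path, sep="\t") -> None:
    s.scores.to_csv(path, sep=sep, index_label="sample_id", float_format="%.8g")


def read_surrogates(path, sep="\t") -> SurrogateScores:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SurrogateScores(df, np.full(df.shape[1], np.nan))
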