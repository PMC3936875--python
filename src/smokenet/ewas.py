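"""Probe-level EWAS: per-probe linear model of beta on smoking status.

Each probe's methylation fraction is regressed on smoking with slide,
plate and cell-mixture surrogate covariates by ordinary least squares;
the smoking coefficient's two-sided t-test p-value is BH-adjusted over
all fitted probes. Probes with too few complete cases or zero residual
variance are skipped and counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .cellmix import SurrogateScores
from .io import BetaMatrix, ProbeAnnotation, SampleSheet
from .stats import bh_adjust

log = logging.getLogger("smokenet")

MIN_COMPLETE_CASES = 10


def _design_matrix(sheet: SampleSheet, sample_ids, surrogates: SurrogateScores | None):
    """Intercept + slide/plate indicator contrasts + PCs + smoker (last).

    Reference level of each categorical is the first by lexical order.
    Covariate columns that add no rank (e.g., plate indicators when plate
    is nested within slide) are aliased out, mirroring how linear-model
    software handles nested batch factors. The smoker column is appended
    last; if it adds no rank the phenotype is perfectly confounded with
    the covariates, which is an error, not something to alias away.
    """
    tab = sheet.table.reindex(sample_ids)
    if tab.isna().any().any():
        raise ValueError("sample sheet does not cover all samples")
    cols = [np.ones(len(tab))]
    names = ["intercept"]
    for var in ("slide", "plate"):
        levels = sorted(pd.unique(tab[var]))
        for lev in levels[1:]:
            cols.append((tab[var] == lev).to_numpy(dtype=float))
            names.append(f"{var}[{lev}]")
    if surrogates is not None:
        sc = surrogates.scores.reindex(sample_ids)
        if sc.isna().any().any():
            raise ValueError("surrogate scores do not cover all samples")
        for c in sc.columns:
            cols.append(sc[c].to_numpy(dtype=float))
            names.append(c)
    x = np.column_stack(cols)
    keep = [0]
    rank = 1
    for j in range(1, x.shape[1]):
        r = np.linalg.matrix_rank(x[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
    if dropped:
        log.info("design: aliased covariate columns dropped: %s", dropped)
    smoker = tab["smoker"].to_numpy(dtype=float)
    design = np.column_stack([x[:, keep], smoker])
    if np.linalg.matrix_rank(design) <= rank:
        raise ValueError("smoking status is perfectly confounded with the covariates "
                         "(rank-deficient design)")
    return design, [names[j] for j in keep] + ["smoker"]


def _ols_t_p(x: np.ndarray, y: np.ndarray, coef_idx: int = 1):
    """OLS of many responses on one design; t and p for one coefficient.

    ``y`` is (n_responses, n_samples) with no NaNs. Returns
    (coef, t, p, ok) where ok flags nonzero residual variance and a
    full-rank design.
    """
    n, k = x.shape
    if np.linalg.matrix_rank(x) < k or n <= k:
        return None
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # (m, k)
    resid = y - beta @ x.T
    dof = n - k
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_idx, coef_idx], 0.0))
    # a numerically-zero residual (constant response) has no valid t-test
    y_var = y.var(axis=1)
    ok = (se > 0) & (y_var > 1e-16) & (sigma2 > 1e-16 * np.maximum(y_var, 1e-30))
    t = np.zeros(y.shape[0])
    t[ok] = beta[ok, coef_idx] / se[ok]
    p = 2.0 * _sps.t.sf(np.abs(t), dof)
    return beta[:, coef_idx], t, p, ok


def fit_probe_models(
    betas: BetaMatrix,
    sheet: SampleSheet,
    surrogates: SurrogateScores | None = None,
    annotation: ProbeAnnotation | None = None,
    min_complete: int = MIN_COMPLETE_CASES,
    m_values: bool = False,
) -> pd.DataFrame:
    """Fit the smoking EWAS model at every probe.

    Returns a DataFrame with one row per fitted probe: probe_id, gene,
    placement, island_status (when an annotation is supplied),
    mean_beta_smokers, mean_beta_nonsmokers, smoking_coefficient,
    t_statistic, raw_p, adjusted_p, n_used. ``adjusted_p`` is BH over
    the fitted probes (m_total = number fitted). The model runs on the
    beta scale by default; ``m_values`` switches the response to
    log2(beta/(1-beta)) with the customary clamping, while group means
    stay on the beta scale.
    """
    sample_ids = betas.sample_ids
    x, names = _design_matrix(sheet, sample_ids, surrogates)
    smoker = sheet.smoker_flags(sample_ids).astype(bool)

    v = betas.masked_values().to_numpy()
    resp = v
    if m_values:
        clamped = np.clip(v, 1e-6, 1 - 1e-6)
        resp = np.log2(clamped / (1 - clamped))
    has_nan = np.isnan(resp).any(axis=1)

    probe_ids = np.asarray(betas.probe_ids)
    coef = np.full(len(probe_ids), np.nan)
    tstat = np.full(len(probe_ids), np.nan)
    rawp = np.full(len(probe_ids), np.nan)
    n_used = np.zeros(len(probe_ids), dtype=int)
    skip_reason: dict[str, str] = {}

    smoker_col = x.shape[1] - 1
    complete = ~has_nan
    if complete.any():
        res = _ols_t_p(x, resp[complete], coef_idx=smoker_col)
        if res is None:
            raise ValueError("rank-deficient design for complete-case probes "
                             "(e.g., slide perfectly confounded with smoking)")
        b, t, p, ok = res
        idx = np.where(complete)[0]
        coef[idx], tstat[idx], rawp[idx] = b, t, p
        n_used[idx] = x.shape[0]
        for i in idx[~ok]:
            skip_reason[probe_ids[i]] = "zero residual variance"
            rawp[i] = np.nan

    for i in np.where(has_nan)[0]:
        keep = ~np.isnan(resp[i])
        if keep.sum() < min_complete:
            skip_reason[probe_ids[i]] = f"fewer than {min_complete} complete cases"
            continue
        res = _ols_t_p(x[keep], resp[i, keep][None, :], coef_idx=smoker_col)
        if res is None:
            skip_reason[probe_ids[i]] = "rank-deficient design"
            continue
        b, t, p, ok = res
        if not ok[0]:
            skip_reason[probe_ids[i]] = "zero residual variance"
            continue
        coef[i], tstat[i], rawp[i] = b[0], t[0], p[0]
        n_used[i] = int(keep.sum())

    fitted = ~np.isnan(rawp)
    if not fitted.any():
        raise ValueError("no probe could be fitted")
    adj = np.full(len(probe_ids), np.nan)
    adj[fitted] = bh_adjust(rawp[fitted])

    with np.errstate(invalid="ignore"):
        mean_s = np.nanmean(v[:, smoker], axis=1)
        mean_n = np.nanmean(v[:, ~smoker], axis=1)

    out = pd.DataFrame({
        "probe_id": probe_ids[fitted],
        "mean_beta_smokers": mean_s[fitted],
        "mean_beta_nonsmokers": mean_n[fitted],
        "smoking_coefficient": coef[fitted],
        "t_statistic": tstat[fitted],
        "raw_p": np.clip(rawp[fitted], np.finfo(float).tiny, 1.0),
        "adjusted_p": adj[fitted],
        "n_used": n_used[fitted],
    })
    if annotation is not None:
        ann = annotation.table.reindex(out["probe_id"])
        out["gene"] = [";".join(g) if isinstance(g, tuple) else "" for g in ann["gene_symbols"]]
        out["placement"] = ann["placement"].to_numpy()
        out["island_status"] = ann["island_status"].to_numpy()
    if skip_reason:
        log.info("fit_probe_models: %d probes skipped (%s)", len(skip_reason),
                 pd.Series(list(skip_reason.values())).value_counts().to_dict())
    out.attrs["skipped"] = skip_reason
    out.attrs["m_total"] = int(fitted.sum())
    return out


def summarize_counts(results: pd.DataFrame, alpha: float = 0.05) -> tuple[int, float]:
    """Number of probes with BH-adjusted p <= alpha, and the threshold used."""
    return int((results["adjusted_p"] <= alpha).sum()), alpha
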