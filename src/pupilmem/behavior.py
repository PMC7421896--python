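"""Scoring of the three memory tests and their group statistics.

Order memory: proportion of correct recency discriminations per condition.
Distance memory: mean of the 1 (very close) .. 4 (very far) ratings.
Source memory: proportion of correct ear judgments per item type, analysed
with a one-way repeated-measures ANOVA over the four item types followed by
Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import ITEM_TYPES
from .dataio import DataError
from .evoked import paired_contrast, against_baseline

log = logging.getLogger("pupilmem")

__all__ = ["score_order", "score_distance", "score_source", "condition_tests",
           "rm_anova_oneway", "hotelling_rm"]


def _per_cell(df: pd.DataFrame, by: str, value: str, agg: str) -> pd.DataFrame:
    out = df.groupby(["participant", by], as_index=False)[value].agg(agg)
    return out.rename(columns={value: "score"})


def score_order(pairs: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per participant x pair condition."""
    return _per_cell(pairs, "pair_condition", "order_correct", "mean")


def score_distance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean 1-4 distance rating per participant x pair condition."""
    if not pairs["distance_rating"].isin([1, 2, 3, 4]).all():
        raise DataError("distance_rating outside 1..4")
    return _per_cell(pairs, "pair_condition", "distance_rating", "mean")


def score_source(items: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per participant x item type."""
    return _per_cell(items, "item_type", "source_correct", "mean")


def _wide(scores: pd.DataFrame, by: str, levels) -> pd.DataFrame:
    wide = scores.pivot(index="participant", columns=by, values="score")
    missing = wide[list(levels)].isna().any(axis=1)
    if missing.any():
        log.warning("excluding %d participant(s) with missing cells listwise",
                    int(missing.sum()))
    return wide.loc[~missing, list(levels)]


def rm_anova_oneway(wide: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA (univariate), with Greenhouse-Geisser.

    Returns F, df, p, partial eta squared, plus GG-corrected values.
    """
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    eps = 1e-12 * max(ss_tot, 1.0)
    if ms_err > eps:
        F = ms_cond / ms_err
    else:
        F = 0.0 if ss_cond <= eps else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    # Greenhouse-Geisser epsilon from the double-centered covariance
    cov = np.cov(y, rowvar=False)
    cc = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    denom = (k - 1) * (cc ** 2).sum()
    eps = float(np.trace(cc) ** 2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    eta_p = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    return dict(F=float(F), df1=df1, df2=df2, p=p, partial_eta_sq=eta_p,
                gg_epsilon=eps, p_gg=p_gg, n=n,
                ss=dict(condition=float(ss_cond), subject=float(ss_subj),
                        error=float(ss_err), total=float(ss_tot)))


def hotelling_rm(wide: pd.DataFrame) -> dict:
    """Multivariate (Hotelling) test of equal condition means.

    One-sample Hotelling T^2 on the k-1 successive differences; emitted
    alongside the univariate ANOVA because the two df conventions
    (F(k-1, n-k+1) vs F(k-1, (k-1)(n-1))) differ.
    """
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    d = np.diff(y, axis=1)
    p_dim = k - 1
    if n <= p_dim:
        return dict(F=np.nan, df1=p_dim, df2=n - p_dim, p=np.nan, n=n)
    dbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False)
    try:
        t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    except np.linalg.LinAlgError:
        return dict(F=np.nan, df1=p_dim, df2=n - p_dim, p=np.nan, n=n)
    F = t2 * (n - p_dim) / (p_dim * (n - 1))
    p = float(stats.f.sf(F, p_dim, n - p_dim))
    return dict(F=float(F), df1=p_dim, df2=n - p_dim, p=p, t2=t2, n=n)


def condition_tests(order_scores: pd.DataFrame, distance_scores: pd.DataFrame,
                    source_scores: pd.DataFrame) -> dict:
    """Group statistics bundle for the three memory tests.

    Paired t-tests (boundary-spanning vs same-context) for order and
    distance; one-sample tests of order accuracy against chance (0.5); the
    source-memory ANOVA over the four item types with Bonferroni-adjusted
    pairwise comparisons (family = the 6 item-type pairs).
    """
    out = {}
    pair_levels = ("boundary_span", "same_context")
    ow = _wide(order_scores, "pair_condition", pair_levels)
    dw = _wide(distance_scores, "pair_condition", pair_levels)
    out["order_boundary_vs_same"] = paired_contrast(
        ow["boundary_span"].to_numpy(), ow["same_context"].to_numpy())
    out["distance_boundary_vs_same"] = paired_contrast(
        dw["boundary_span"].to_numpy(), dw["same_context"].to_numpy())
    out["order_vs_chance"] = {
        cond: against_baseline(ow[cond].to_numpy(), mu0=0.5) for cond in pair_levels}

    sw = _wide(source_scores, "item_type", ITEM_TYPES)
    out["source_anova"] = rm_anova_oneway(sw)
    out["source_anova_multivariate"] = hotelling_rm(sw)
    n_family = len(list(itertools.combinations(ITEM_TYPES, 2)))
    pairwise = {}
    for a, b in itertools.combinations(ITEM_TYPES, 2):
        res = paired_contrast(sw[a].to_numpy(), sw[b].to_numpy())
        if np.isfinite(res.get("p", np.nan)):
            res["p_bonferroni"] = float(min(res["p"] * n_family, 1.0))
        else:
            res["p_bonferroni"] = np.nan
        pairwise[f"{a}_vs_{b}"] = res
    out["source_pairwise"] = pairwise
    return out
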