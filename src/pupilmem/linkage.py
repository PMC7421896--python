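"""Pupil-memory association analyses.

Subtraction scores (participant boundary-minus-same-context deltas) feed
two-tailed Spearman correlations between pupil component scores and memory
measures.  Trial-level analyses are mixed models with a participant random
intercept: logistic (Gauss-Hermite maximum likelihood) for binary outcomes,
linear (:class:`statsmodels` MixedLM) for distance ratings.  The exact
supplementary model specifications are not in the source report; the
structure here is the minimal one consistent with it and is labelled as a
reconstruction in every summary.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

log = logging.getLogger("pupilmem")

__all__ = ["spearman", "subtraction_scores", "pupil_memory_correlations",
           "mixed_model", "trial_measures", "trial_level_models",
           "pitch_change_analysis", "stability_analysis"]

MEMORY_MEASURES = ("order", "distance", "source")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y, method: str = "auto") -> dict:
    """Spearman rank correlation with midrank ties, two-tailed p.

    ``method='t'`` uses the t approximation; ``'exact'`` enumerates all
    permutations (n <= 10); ``'auto'`` picks exact for n <= 10 with no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError(f"need n >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return dict(rho=np.nan, p=np.nan, n=n, zero_variance=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if method == "exact" or (method == "auto" and n <= 10 and not ties):
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        # vectorized full enumeration: corr with fixed rx is linear in the
        # permuted ry, so a single matmul scores every permutation
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
        ry_perm = ry[perms]
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        r_all = (ry_perm - ry.mean()) @ rx_c / denom
        p = float(np.mean(np.abs(r_all) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
    return dict(rho=rho, p=float(p), n=n, zero_variance=False)


# ---------------------------------------------------------------------------
# subtraction scores
# ---------------------------------------------------------------------------

def subtraction_scores(component_scores: pd.DataFrame,
                       order_scores: pd.DataFrame,
                       distance_scores: pd.DataFrame,
                       source_scores: pd.DataFrame) -> pd.DataFrame:
    """Boundary minus same-context deltas, one row per participant.

    ``component_scores`` must have columns participant, tone_condition and
    score_1..score_k.  Memory frames are the per-cell outputs of the
    behavior scorers.
    """
    if component_scores.duplicated(["participant", "tone_condition"]).any():
        raise ValueError("duplicate participant/condition rows in component scores")
    score_cols = [c for c in component_scores.columns if c.startswith("score_")]
    wide = component_scores.pivot(index="participant", columns="tone_condition",
                                  values=score_cols)
    out = pd.DataFrame(index=wide.index)
    for col in score_cols:
        out["d" + col] = wide[(col, "boundary")] - wide[(col, "same_context")]

    def delta(scores, by, a, b):
        w = scores.pivot(index="participant", columns=by, values="score")
        return w[a] - w[b]

    out["dorder"] = delta(order_scores, "pair_condition", "boundary_span", "same_context")
    out["ddistance"] = delta(distance_scores, "pair_condition",
                             "boundary_span", "same_context")
    out["dsource"] = delta(source_scores, "item_type", "boundary", "same_context")
    return out.reset_index()


def pupil_memory_correlations(subtractions: pd.DataFrame,
                              mode: str = "pooled") -> pd.DataFrame:
    """All component x memory-measure Spearman correlations.

    No multiple-testing adjustment is applied (flagged in the output), so
    p-values are nominal per-cell rates.
    """
    if subtractions["participant"].duplicated().any():
        raise ValueError("duplicate participants in subtraction scores")
    comp_cols = sorted(c for c in subtractions.columns if c.startswith("dscore_"))
    rows = []
    for comp in comp_cols:
        for measure, col in [("order", "dorder"), ("distance", "ddistance"),
                             ("source", "dsource")]:
            res = spearman(subtractions[comp], subtractions[col], method="t")
            rows.append(dict(component=int(comp.split("_")[1]),
                             memory_measure=measure, rho=res["rho"],
                             p=res["p"], n=res["n"], mode=mode,
                             multiple_comparison_correction="none"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(21)
_GH_W = _GH_W / _GH_W.sum()


def _logistic_ri_loglik(params, y, X, group_idx, n_groups):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta
    # log-lik per group integrated over u ~ N(0, sigma^2) by Gauss-Hermite
    ll = 0.0
    lin = eta[:, None] + sigma * _GH_X[None, :]
    logp = -np.logaddexp(0.0, -lin)
    log1mp = -np.logaddexp(0.0, lin)
    contrib = np.where(y[:, None] > 0, logp, log1mp)
    per_group = np.zeros((n_groups, len(_GH_X)))
    np.add.at(per_group, group_idx, contrib)
    m = per_group.max(axis=1, keepdims=True)
    ll = np.sum(m.squeeze(1) + np.log(np.exp(per_group - m) @ _GH_W))
    return -ll


def mixed_model(df: pd.DataFrame, outcome: str, predictors: list[str],
                binary: bool, group: str = "participant") -> dict:
    """Random-intercept mixed model with standardized predictors.

    Binary outcomes: logistic random-intercept model fitted by adaptive-free
    Gauss-Hermite ML with Wald tests from the numerical Hessian.  Continuous
    outcomes: REML linear mixed model via statsmodels.  Degenerate outcomes
    (zero variance) and zero-variance predictors are flagged rather than
    fitted.
    """
    data = df[[group, outcome] + predictors].dropna()
    out = dict(outcome=outcome, predictors=list(predictors), binary=binary,
               n=len(data), n_groups=data[group].nunique(),
               structure="random intercept (reconstruction)")
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        out["degenerate_outcome"] = True
        log.warning("outcome %s has zero variance; model skipped", outcome)
        return out
    Xcols = {}
    for pred in predictors:
        v = data[pred].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            out["zero_variance_predictor"] = pred
            log.warning("predictor %s has zero variance; model skipped", pred)
            return out
        Xcols[pred] = (v - v.mean()) / sd
    X = np.column_stack([np.ones(len(y))] + [Xcols[p] for p in predictors])
    names = ["intercept"] + list(predictors)
    codes, _ = pd.factorize(data[group])
    if binary:
        start = np.zeros(X.shape[1] + 1)
        start[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        res = optimize.minimize(
            _logistic_ri_loglik, start, args=(y, X, codes, codes.max() + 1),
            method="BFGS", options=dict(maxiter=500, gtol=1e-6))
        if not res.success:
            log.warning("logistic mixed model did not fully converge: %s", res.message)
        hess = approx_hess1(res.x, _logistic_ri_loglik,
                            args=(y, X, codes, codes.max() + 1))
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov)[:len(names)], 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        coefs = res.x[:len(names)]
        zs = np.divide(coefs, se, out=np.full_like(coefs, np.nan), where=se > 0)
        out.update(converged=bool(res.success),
                   random_intercept_sd=float(np.exp(res.x[-1])),
                   coefficients={
                       nm: dict(estimate=float(b), se=float(s), z=float(z),
                                p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan)
                       for nm, b, s, z in zip(names, coefs, se, zs)})
    else:
        model = MixedLM(y, X, groups=codes)
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception as err:  # non-convergence fallback: plain OLS, flagged
            log.warning("MixedLM failed (%s); refitting without random effects", err)
            import statsmodels.api as sm
            ols = sm.OLS(y, X).fit()
            out.update(converged=False, simplified="ols",
                       coefficients={nm: dict(estimate=float(b), se=float(s),
                                              z=float(t), p=float(p))
                                     for nm, b, s, t, p in zip(
                                         names, ols.params, ols.bse,
                                         ols.tvalues, ols.pvalues)})
            return out
        out.update(converged=bool(fit.converged),
                   random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
                   coefficients={
                       nm: dict(estimate=float(b), se=float(s), z=float(z),
                                p=float(p))
                       for nm, b, s, z, p in zip(names, fit.fe_params,
                                                 fit.bse_fe, fit.tvalues[:len(names)],
                                                 fit.pvalues[:len(names)])})
    return out


# ---------------------------------------------------------------------------
# trial-level measures and analyses
# ---------------------------------------------------------------------------

def trial_measures(evoked_trials: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Per tone trial: phasic (evoked dilation), tonic (raw pre-tone mean),
    item id, and the boundary pitch change in Hz."""
    tones = events[events["event_type"] == "tone"].copy()
    freq = tones.pivot_table(index=["participant", "block", "event_index"],
                             values="frequency_hz", aggfunc="first")
    prev = freq.groupby(level=["participant", "block"])["frequency_hz"].shift(1)
    freq["pitch_change_hz"] = (freq["frequency_hz"] - prev).abs()
    tones = tones.merge(freq["pitch_change_hz"].reset_index(),
                        on=["participant", "block", "event_index"], how="left")
    tones.loc[tones["tone_condition"] != "boundary", "pitch_change_hz"] = np.nan
    keys = ["participant", "block", "event_index", "position_in_event"]
    merged = evoked_trials.merge(
        tones[keys + ["item_id", "frequency_hz", "pitch_change_hz"]],
        on=keys, how="left")
    merged = merged.rename(columns={"evoked": "phasic"})
    return merged


def trial_level_models(trials: pd.DataFrame, pairs: pd.DataFrame,
                       items: pd.DataFrame) -> dict:
    """Phasic/tonic mixed models for the three memory outcomes.

    Join rules (a reconstruction; the source report does not specify them):
    pair outcomes take the pupil measures of the tone preceding the pair's
    second item; item outcomes take the tone preceding the item itself.
    """
    pair_df = pairs.merge(
        trials[["participant", "block", "item_id", "phasic", "tonic"]],
        left_on=["participant", "block", "item_b"],
        right_on=["participant", "block", "item_id"], how="inner")
    item_df = items.merge(
        trials[["participant", "block", "item_id", "phasic", "tonic"]],
        on=["participant", "block", "item_id"], how="inner")
    return {
        "order": mixed_model(pair_df, "order_correct", ["phasic", "tonic"], binary=True),
        "distance": mixed_model(pair_df, "distance_rating", ["phasic", "tonic"],
                                binary=False),
        "source": mixed_model(item_df, "source_correct", ["phasic", "tonic"],
                              binary=True),
    }


def pitch_change_analysis(trials: pd.DataFrame, items: pd.DataFrame) -> dict:
    """Boundary-only: does the tone pitch change predict evoked dilation or
    boundary-item memory?"""
    btr = trials[trials["pitch_change_hz"].notna()].copy()
    out = {"pupil": mixed_model(btr, "phasic", ["pitch_change_hz"], binary=False)}
    joined = items[items["item_type"] == "boundary"].merge(
        btr[["participant", "block", "item_id", "pitch_change_hz"]],
        on=["participant", "block", "item_id"], how="inner")
    out["source"] = mixed_model(joined, "source_correct", ["pitch_change_hz"],
                                binary=True)
    return out


def _pair_spans(pairs: pd.DataFrame, events: pd.DataFrame,
                image_duration_ms: float = 2500.0) -> pd.DataFrame:
    images = events[events["event_type"] == "image"]
    on = images.set_index(["participant", "block", "item_id"])["onset_ms"]
    key_a = pd.MultiIndex.from_frame(pairs[["participant", "block", "item_a"]])
    key_b = pd.MultiIndex.from_frame(pairs[["participant", "block", "item_b"]])
    out = pairs.copy()
    out["span_start_ms"] = on.reindex(key_a).to_numpy()
    out["span_stop_ms"] = on.reindex(key_b).to_numpy() + image_duration_ms
    return out


def stability_analysis(recordings, pairs: pd.DataFrame, events: pd.DataFrame) -> dict:
    """Pupil s.d. over each tested pair's encoding span, and its relation to
    temporal memory.

    Span = [first-item onset, second-item offset].  Sign convention: a
    positive distance coefficient means higher variability goes with larger
    rated distance.  Pairs whose span exceeds the recording are dropped.
    """
    spans = _pair_spans(pairs, events)
    rec_map = {rec.key: rec for rec in recordings}
    sds = np.full(len(spans), np.nan)
    for i, row in enumerate(spans.itertuples(index=False)):
        rec = rec_map.get((row.participant, row.block))
        if rec is None:
            continue
        step = 1000.0 / rec.sampling_rate
        t0 = float(rec.time[0])
        a = int(round((row.span_start_ms - t0) / step))
        b = int(round((row.span_stop_ms - t0) / step))
        if a < 0 or b > rec.n_samples:
            log.warning("pair span outside recording for %s; dropped", rec.key)
            continue
        sds[i] = rec.pupil[a:b].std(ddof=0)
    spans["pair_pupil_sd"] = sds
    spans = spans.dropna(subset=["pair_pupil_sd"])
    return {
        "pair_sd": spans[["participant", "block", "item_a", "item_b",
                          "pair_condition", "pair_pupil_sd"]],
        "distance": mixed_model(spans, "distance_rating", ["pair_pupil_sd"],
                                binary=False),
        "order": mixed_model(spans, "order_correct", ["pair_pupil_sd"], binary=True),
    }
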