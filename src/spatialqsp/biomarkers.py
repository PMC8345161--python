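"""Biomarker discovery on virtual-cohort endpoint tables.

Three endpoint families are supported, each with its regression model:
continuous endpoints (final tumor diameter) use ordinary least squares,
binary responder status uses logistic regression, and time-to-progression
uses a Cox proportional-hazards model.  Candidate biomarkers enter or
leave the model by stepwise selection driven by likelihood-ratio tests
(LRT) of nested fits; robustness is assessed by repeating forward
selection on resampled cohorts and reporting per-candidate selection
frequencies.  Subgroup summaries dichotomize the cohort at the biomarker
median and report family-appropriate effect measures with 95% intervals
(t-based mean CI, Wilson score interval for response rates, log hazard
ratio from a single-covariate Cox fit).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.api import OLS, Logit, add_constant
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "StepRecord",
    "forward_select",
    "backward_select",
    "resample_selection",
    "subgroup_summary",
    "responder_vs_nonresponder_test",
    "lrt_pvalue",
]

FAMILIES = ("linear", "logistic", "cox")


@dataclass(frozen=True)
class StepRecord:
    step: int
    action: str  # "add" | "drop"
    candidate: str
    lrt_stat: float
    p_value: float


def _loglik(
    table: pd.DataFrame, endpoint: str, family: str, covariates: list[str]
) -> float:
    """Maximized log-likelihood of the family model with given covariates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "linear":
            X = add_constant(table[covariates], has_constant="add")
            return float(OLS(table[endpoint], X).fit().llf)
        if family == "logistic":
            X = add_constant(table[covariates], has_constant="add")
            return float(
                Logit(table[endpoint].astype(float), X).fit(disp=0, maxiter=200).llf
            )
        if family == "cox":
            if not covariates:
                return _cox_null_loglik(
                    table[endpoint].to_numpy(dtype=float),
                    table[f"{endpoint}_event"].to_numpy(dtype=bool),
                )
            cph = CoxPHFitter(penalizer=1e-6)
            cols = [endpoint, f"{endpoint}_event"] + covariates
            cph.fit(table[cols], duration_col=endpoint, event_col=f"{endpoint}_event")
            return float(cph.log_likelihood_)
    raise ValueError(f"unknown family {family!r}")


def _cox_null_loglik(durations: np.ndarray, events: np.ndarray) -> float:
    """Cox partial log-likelihood at beta = 0 with Efron tie handling.

    At the null all relative hazards are 1, so each of the d tied events
    at a time with risk-set size n_R contributes -log(n_R - l), l = 0..d-1
    (identical to Breslow only when d = 1).  Matches lifelines' default
    tie convention so nested LRTs against fitted models are consistent.
    """
    order = np.argsort(durations)
    d_sorted = durations[order]
    e_sorted = events[order]
    n = len(d_sorted)
    ll = 0.0
    for t in np.unique(d_sorted[e_sorted]):
        n_risk = n - int(np.searchsorted(d_sorted, t, side="left"))
        d_ties = int(np.sum((d_sorted == t) & e_sorted))
        for l in range(d_ties):
            ll -= np.log(n_risk - l)
    return float(ll)


def lrt_pvalue(ll_full: float, ll_reduced: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square p-value for nested fits."""
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def forward_select(
    table: pd.DataFrame,
    endpoint: str,
    candidates: list[str],
    family: str = "linear",
    alpha: float = 0.05,
) -> tuple[list[str], list[StepRecord]]:
    """Forward stepwise selection by LRT.

    Starting from the intercept-only model, each step adds the candidate
    with the smallest LRT p-value against the current model, stopping when
    no remaining candidate reaches p < alpha.  Deterministic given the
    table (ties broken by candidate order).
    """
    _validate_family(family)
    selected: list[str] = []
    remaining = list(candidates)
    log: list[StepRecord] = []
    ll_current = _loglik(table, endpoint, family, selected)
    step = 0
    while remaining:
        best: tuple[float, float, str] | None = None
        for cand in remaining:
            try:
                ll = _loglik(table, endpoint, family, selected + [cand])
            except Exception:  # noqa: BLE001 - non-convergent fit: skip, log
                logger.warning("fit failed for candidate %s; skipped", cand)
                continue
            stat, p = lrt_pvalue(ll, ll_current)
            if best is None or p < best[1]:
                best = (stat, p, cand)
        if best is None or best[1] >= alpha:
            break
        stat, p, cand = best
        step += 1
        selected.append(cand)
        remaining.remove(cand)
        ll_current = _loglik(table, endpoint, family, selected)
        log.append(StepRecord(step, "add", cand, stat, p))
    return selected, log


def backward_select(
    table: pd.DataFrame,
    endpoint: str,
    candidates: list[str],
    family: str = "linear",
    alpha: float = 0.05,
) -> tuple[list[str], list[StepRecord]]:
    """Backward elimination: drop the least significant candidate while p > alpha."""
    _validate_family(family)
    selected = list(candidates)
    log: list[StepRecord] = []
    step = 0
    while selected:
        ll_full = _loglik(table, endpoint, family, selected)
        worst: tuple[float, float, str] | None = None
        for cand in selected:
            reduced = [c for c in selected if c != cand]
            ll_red = _loglik(table, endpoint, family, reduced)
            stat, p = lrt_pvalue(ll_full, ll_red)
            if worst is None or p > worst[1]:
                worst = (stat, p, cand)
        assert worst is not None
        stat, p, cand = worst
        if p <= alpha:
            break
        step += 1
        selected.remove(cand)
        log.append(StepRecord(step, "drop", cand, stat, p))
    return selected, log


def resample_selection(
    table: pd.DataFrame,
    endpoint: str,
    candidates: list[str],
    family: str = "linear",
    alpha: float = 0.05,
    n_rep: int = 100,
    frac: float = 0.9,
    seed: int | None = None,
) -> pd.Series:
    """Selection frequency over with-replacement resamples of size 0.9 n.

    Resampling with replacement to 90% of the cohort size (a deliberately
    literal, slightly unconventional bootstrap variant) followed by
    forward selection; returns the per-candidate selection percentage.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(frac * len(table)))
    counts = {c: 0 for c in candidates}
    for _ in range(n_rep):
        idx = rng.integers(0, len(table), size=m)
        sub = table.iloc[idx].reset_index(drop=True)
        try:
            chosen, _ = forward_select(sub, endpoint, candidates, family, alpha)
        except Exception:  # noqa: BLE001
            logger.warning("selection failed on a resample; counted as empty")
            chosen = []
        for c in chosen:
            counts[c] += 1
    return pd.Series({c: 100.0 * counts[c] / n_rep for c in candidates}, name="pct_selected")


def subgroup_summary(
    table: pd.DataFrame,
    biomarker: str,
    endpoint: str,
    family: str = "linear",
) -> pd.DataFrame:
    """Median-dichotomized subgroup effects, one forest row per subgroup.

    Ties at the median fall in the lower subgroup.  Returns per-subgroup
    point estimates with 95% CI: subgroup means (t interval) for linear,
    ORR with Wilson score interval for logistic, and the log hazard ratio
    of high vs low from a single-covariate Cox fit (repeated on both rows)
    for cox.
    """
    _validate_family(family)
    values = table[biomarker].to_numpy(dtype=float)
    med = float(np.median(values))
    low = table[values <= med]
    high = table[values > med]
    if len(low) < 4 or len(high) < 4:
        raise ValueError("need at least 4 patients per subgroup")
    rows = []
    if family == "linear":
        for name, sub in (("low", low), ("high", high)):
            y = sub[endpoint].to_numpy(dtype=float)
            mean = float(np.mean(y))
            half = stats.t.ppf(0.975, len(y) - 1) * stats.sem(y) if len(y) > 1 else np.inf
            rows.append(
                {"subgroup": name, "n": len(y), "estimate": mean,
                 "ci_low": mean - half, "ci_high": mean + half, "measure": "mean"}
            )
    elif family == "logistic":
        for name, sub in (("low", low), ("high", high)):
            k = int(sub[endpoint].sum())
            n = len(sub)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append(
                {"subgroup": name, "n": n, "estimate": k / n,
                 "ci_low": float(lo), "ci_high": float(hi), "measure": "orr",
                 "unbounded_ci": k in (0, n)}
            )
    else:  # cox
        df = table[[endpoint, f"{endpoint}_event"]].copy()
        df["high"] = (values > med).astype(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col=endpoint, event_col=f"{endpoint}_event")
        log_hr = float(cph.params_["high"])
        ci = cph.confidence_intervals_
        lo = float(ci.iloc[0, 0])
        hi = float(ci.iloc[0, 1])
        for name, sub in (("low", low), ("high", high)):
            rows.append(
                {"subgroup": name, "n": len(sub), "estimate": log_hr,
                 "ci_low": lo, "ci_high": hi, "measure": "log_hr_high_vs_low"}
            )
    out = pd.DataFrame(rows)
    out.insert(0, "biomarker", biomarker)
    return out


def responder_vs_nonresponder_test(table: pd.DataFrame, biomarker: str) -> float:
    """Two-sided Mann-Whitney U p-value comparing biomarker distributions.

    Midranks for ties, normal approximation with continuity correction.
    """
    resp = table.loc[table["responder"].astype(bool), biomarker].to_numpy(dtype=float)
    nonresp = table.loc[~table["responder"].astype(bool), biomarker].to_numpy(dtype=float)
    if len(resp) == 0 or len(nonresp) == 0:
        raise ValueError("both responder groups must be nonempty")
    res = stats.mannwhitneyu(
        resp, nonresp, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _validate_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
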