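"""Kaplan-Meier, log-rank and Cox proportional-hazards wrappers.

Partial-likelihood fitting is delegated to lifelines (Efron tie
handling); this module owns the interface: factor covariates with
explicit reference levels (reference rows are emitted in the hazard
table), interaction terms, quartile stratification of continuous scores
(boundary ties fall into the lower stratum), and the correlation-panel /
rank-sum utilities used for expression-burden and PSI-age associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class KmResult:
    curves: dict            # group -> survival function DataFrame
    logrank_p: float        # NaN when undefined (no events)
    n_events: int


def km_logrank(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    group_col: str,
) -> KmResult:
    """Product-limit curves per group plus the two-sided log-rank p."""
    groups = df[group_col]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for g, sub in df.groupby(group_col):
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = km.survival_function_
    n_events = int(df[event_col].sum())
    if n_events == 0:
        logger.warning("all observations censored; log-rank p undefined")
        return KmResult(curves=curves, logrank_p=np.nan, n_events=0)
    res = multivariate_logrank_test(df[time_col], groups, df[event_col])
    return KmResult(curves=curves, logrank_p=float(res.p_value), n_events=n_events)


def _build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    factors: Mapping[str, str] | None,
    interactions: Sequence[tuple[str, str]] | None,
):
    """Expand factor covariates to treatment-coded dummies and add products.

    Returns (design DataFrame, reference rows, mapping term -> source).
    """
    factors = dict(factors or {})
    design = pd.DataFrame(index=df.index)
    ref_rows = []
    col_of: dict[str, list[str]] = {}
    for cov in covariates:
        if cov in factors:
            ref = factors[cov]
            levels = sorted(df[cov].astype(str).unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov!r}")
            cols = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}[{lev}]"
                design[name] = (df[cov].astype(str) == lev).astype(float)
                cols.append(name)
            col_of[cov] = cols
            ref_rows.append({"term": f"{cov}[{ref}]", "is_reference": True})
        else:
            design[cov] = df[cov].astype(float)
            col_of[cov] = [cov]
    for a, b in interactions or []:
        for ca in col_of[a]:
            for cb in col_of[b]:
                design[f"{ca}:{cb}"] = design[ca] * design[cb]
    return design, ref_rows


def cox_fit(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: Sequence[str],
    factors: Mapping[str, str] | None = None,
    interactions: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Cox PH fit; returns a hazard table (HR, 95% CI, Wald p per term).

    ``factors`` maps covariate name -> reference level; reference rows are
    included with ``is_reference=True`` so forest plots can show them.
    """
    design, ref_rows = _build_design(df, covariates, factors, interactions)
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant in the risk set")
    if int(df[event_col].sum()) < design.shape[1]:
        raise ValueError("fewer events than model terms")
    fit_df = design.copy()
    fit_df["_time"] = df[time_col].to_numpy(dtype=float)
    fit_df["_event"] = df[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="_time", event_col="_event")
    summ = cph.summary
    rows = []
    for term in summ.index:
        rows.append({
            "term": term,
            "hazard_ratio": float(summ.loc[term, "exp(coef)"]),
            "ci_low": float(summ.loc[term, "exp(coef) lower 95%"]),
            "ci_high": float(summ.loc[term, "exp(coef) upper 95%"]),
            "p": float(summ.loc[term, "p"]),
            "is_reference": False,
        })
    for r in ref_rows:
        rows.append({"term": r["term"], "hazard_ratio": 1.0,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                     "is_reference": True})
    return pd.DataFrame(rows)


def quartile_strata(x: pd.Series) -> pd.Series:
    """Cohort-quartile stratum (Q1..Q4); boundary ties go to the lower stratum."""
    qs = np.percentile(x.dropna(), [25, 50, 75])
    if len(np.unique(qs)) < 3:
        raise ValueError(f"quartile boundaries collapse under ties: {qs}")
    # x <= q1 -> Q1; q1 < x <= q2 -> Q2; etc.
    stratum = 1 + (x.to_numpy()[:, None] > qs[None, :]).sum(axis=1)
    out = pd.Series([f"Q{s}" for s in stratum], index=x.index)
    return out.where(x.notna(), other=pd.NA)


def quartile_model(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    score_col: str,
    covariates: Sequence[str] = (),
    factors: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cox fit on the quartile factor of ``score_col`` with Q1 reference."""
    if len(df) < 8:
        raise ValueError("need at least 8 samples for quartile stratification")
    work = df.copy()
    work["_quartile"] = quartile_strata(work[score_col])
    work = work[work["_quartile"].notna()]
    factors = dict(factors or {})
    factors["_quartile"] = "Q1"
    table = cox_fit(
        work, time_col, event_col,
        covariates=["_quartile", *covariates], factors=factors,
    )
    table["term"] = table["term"].str.replace("_quartile", score_col + "_quartile",
                                              regex=False)
    return table


def correlate_panel(
    x_matrix: pd.DataFrame,
    y: pd.Series,
    method: str = "pearson",
    adjust: str = "fdr_bh",
    log2_x: bool = False,
    log2_y: bool = False,
) -> pd.DataFrame:
    """Per-gene correlation of a gene x sample panel against a sample vector.

    Pairwise-complete; zero-variance genes are excluded from the FDR and
    reported with missing r.  ``log2_*`` apply log2(v + 1) first.
    """
    shared = x_matrix.columns.intersection(y.index)
    yv = y.loc[shared].astype(float)
    if log2_y:
        yv = np.log2(yv + 1)
    rows = []
    for gene in x_matrix.index:
        xv = x_matrix.loc[gene, shared].astype(float)
        if log2_x:
            xv = np.log2(xv + 1)
        ok = xv.notna() & yv.notna()
        n = int(ok.sum())
        if n < 3 or xv[ok].std(ddof=1) == 0 or yv[ok].std(ddof=1) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan, "n": n})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(xv[ok], yv[ok])
        elif method == "spearman":
            r, p = stats.spearmanr(xv[ok], yv[ok])
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"gene": gene, "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method=adjust)[1]
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%d genes excluded from FDR (undefined correlation)", n_dropped)
    return out


def compare_psi_groups(
    psi: pd.Series,
    groups: pd.Series,
    group_order: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Pairwise rank-sum tests across ordered groups plus a trend summary.

    Groups are ordinal (e.g. age categories); the trend is the Spearman
    correlation of PSI against the group's ordinal position.
    """
    groups = groups.loc[psi.index]
    for g in group_order:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    rows = []
    for i, a in enumerate(group_order):
        for b in group_order[i + 1:]:
            xa = psi[groups == a].dropna()
            xb = psi[groups == b].dropna()
            if xa.nunique() <= 1 and xb.nunique() <= 1 and \
                    set(xa.unique()) == set(xb.unique()):
                p, u = 1.0, np.nan
            else:
                u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({
                "group_a": a, "group_b": b,
                "median_a": float(xa.median()), "median_b": float(xb.median()),
                "u": float(u) if np.isfinite(u) else np.nan, "p": float(p),
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    ordinal = groups.map({g: i for i, g in enumerate(group_order)})
    rho, trend_p = stats.spearmanr(psi, ordinal, nan_policy="omit")
    return out, {"spearman_rho": float(rho), "trend_p": float(trend_p)}
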