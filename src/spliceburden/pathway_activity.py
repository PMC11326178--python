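"""Single-sample gene-set activity scores and group comparisons.

The score is a deterministic ssGSEA-style running-sum statistic: per
sample, genes are ranked by expression (descending, average ranks on
ties); walking down the ranked list, in-set genes add their rank weight
``rank**alpha`` (normalized to sum to 1 over the set) and out-of-set
genes subtract ``1/(N - |S|)``; the score is the sum of the running sum
over all steps (the integral form).  With ``alpha = 0`` this reduces to a
Kolmogorov-Smirnov-type statistic.  Being rank-based, scores are
invariant to any strictly monotone transform of a sample's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if genes:
                sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def _sample_score(expr: pd.Series, in_set: np.ndarray, alpha: float) -> float:
    n = len(expr)
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        return np.nan
    ranks = stats.rankdata(expr.to_numpy(), method="average")  # 1 = lowest
    # deterministic walk: descending expression, gene-name tie-break
    order = np.lexsort((expr.index.to_numpy(), -expr.to_numpy()))
    w = ranks[order] ** alpha
    members = in_set[order]
    inc = np.where(members, w, 0.0)
    denom = inc.sum()
    inc = inc / denom
    dec = np.where(members, 0.0, 1.0 / (n - n_in))
    running = np.cumsum(inc - dec)
    return float(running.sum())


def single_sample_score(
    expr: pd.DataFrame,
    sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ScoreTable: samples x gene sets.

    ``expr`` is a gene x sample matrix (e.g. TPM).  Set genes missing
    from the matrix are ignored with a warning; a set with no overlap at
    all yields missing scores.  ``normalize`` rescales each set's scores
    to the cohort [0, 1] range.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least two genes")
    out = pd.DataFrame(index=expr.columns, dtype=float)
    gene_index = expr.index
    for gs in sets:
        present = gene_index.isin(gs.genes)
        n_missing = len(gs.genes) - int(present.sum())
        if present.sum() == 0:
            logger.warning("gene set %r shares no genes with the matrix", gs.name)
            out[gs.name] = np.nan
            continue
        if n_missing:
            logger.info("gene set %r: %d genes absent from matrix", gs.name, n_missing)
        scores = np.array([
            _sample_score(expr[c], present, alpha) for c in expr.columns
        ])
        if normalize and np.isfinite(scores).any():
            lo, hi = np.nanmin(scores), np.nanmax(scores)
            if hi > lo:
                scores = (scores - lo) / (hi - lo)
        out[gs.name] = scores
    out.index.name = "sample_id"
    return out


def compare_scores(
    scores: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest Welch test per gene set x group.

    The primary effect size is the group-vs-rest mean difference; a log2
    ratio on positively shifted scores (shift = 1 - global minimum) is
    reported secondarily since raw running-sum scores can be negative.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[scores.index]
    shift = 1.0 - np.nanmin(scores.to_numpy()) if scores.size else 1.0
    rows = []
    for gs in scores.columns:
        vec = scores[gs]
        for g in sorted(groups.unique()):
            a = vec[groups == g].dropna()
            b = vec[groups != g].dropna()
            if len(a) < 2 or len(b) < 2:
                logger.warning("group %r too small for %r; skipped", g, gs)
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            mean_diff = float(a.mean() - b.mean())
            log2fc = float(np.log2((a.mean() + shift) / (b.mean() + shift)))
            rows.append({
                "gene_set": gs, "group": g, "n_group": len(a),
                "mean_diff": mean_diff, "log2fc_shifted": log2fc,
                "t": float(t), "p": float(p),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method=adjust)[1]
    return out


def correlate_score_with_abundance(
    scores: pd.Series,
    abundance: pd.DataFrame,
    pathway_genes: Sequence[str],
) -> tuple[float, float, int]:
    """Pearson r between pathway score and mean protein abundance.

    Summarizes the protein x sample abundance matrix as the per-sample
    mean over the pathway's proteins, on the shared-sample intersection
    (pairwise complete).
    """
    genes = [g for g in pathway_genes if g in abundance.index]
    if not genes:
        raise ValueError("no pathway genes in abundance matrix")
    mean_ab = abundance.loc[genes].mean(axis=0, skipna=True)
    shared = scores.index.intersection(mean_ab.index)
    x = scores.loc[shared]
    y = mean_ab.loc[shared]
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 shared samples, got {n}")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), n
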