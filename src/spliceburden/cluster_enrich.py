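"""Variable-event selection, hierarchical clustering, label enrichment.

Samples are clustered on the PSI values of the most variable skipped-exon
events (default top 5,000) with Ward linkage on Euclidean distances after
event-mean imputation of missing cells.  Cluster/label association is a
two-sided Fisher exact test on the 2x2 membership table with the sample
odds ratio (a*d)/(b*c); a Haldane 0.5 correction is applied (and flagged)
when any cell is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .rmats_io import PsiMatrix

logger = logging.getLogger(__name__)


def select_variable_events(m: PsiMatrix, k_events: int = 5000) -> PsiMatrix:
    """Top ``k_events`` rows by PSI variance over measured samples.

    Ties are broken by event-key lexicographic order so the selection is
    deterministic and invariant to sample order.
    """
    values = m.values
    var = values.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    if k_events > len(values):
        logger.warning("requested %d events but only %d available; keeping all",
                       k_events, len(values))
        k_events = len(values)
    # stable sort on descending variance after lexicographic pre-sort,
    # so tied variances resolve in event-key order
    order = var.loc[sorted(var.index)].sort_values(ascending=False, kind="stable")
    keep = order.index[:k_events]
    keep = values.index[values.index.isin(keep)]  # preserve original row order
    return PsiMatrix(values=values.loc[keep], support=m.support.loc[keep],
                     events=m.events.loc[keep])


def impute_event_mean(values: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the event (row) mean; all-missing rows get 0.5."""
    row_mean = values.mean(axis=1, skipna=True).fillna(0.5)
    return values.apply(lambda col: col.fillna(row_mean))


@dataclass
class ClusterAssignment:
    labels: pd.Series          # sample_id -> cluster id in 1..k
    k: int
    linkage_method: str
    distance_metric: str
    silhouette_profile: pd.Series | None = None  # k -> mean silhouette


def _linkage_matrix(m: PsiMatrix, linkage_method: str, metric: str):
    filled = impute_event_mean(m.values)
    # samples are observations: cluster the transposed matrix
    x = filled.to_numpy(dtype=float).T
    return x, linkage(x, method=linkage_method, metric=metric)


def hierarchical_cluster(
    m: PsiMatrix,
    k: int | None = None,
    linkage_method: str = "ward",
    metric: str = "euclidean",
    k_range: tuple[int, int] = (2, 15),
) -> ClusterAssignment:
    """Agglomerative clustering of samples cut into ``k`` clusters.

    When ``k`` is None, k is chosen in ``k_range`` by maximizing the mean
    silhouette width, and the full profile is reported.
    """
    n = m.n_samples
    if k is not None and (k < 2 or k > n):
        raise ValueError(f"k={k} out of range for {n} samples")
    x, tree = _linkage_matrix(m, linkage_method, metric)

    profile = None
    if k is None:
        lo, hi = k_range
        hi = min(hi, n - 1)
        scores = {}
        for kk in range(lo, hi + 1):
            lab = fcluster(tree, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            scores[kk] = float(silhouette_score(x, lab, metric=metric))
        if not scores:
            raise ValueError("could not evaluate any k in range")
        profile = pd.Series(scores, name="mean_silhouette")
        k = int(profile.idxmax())

    raw = fcluster(tree, t=k, criterion="maxclust")
    # contiguous ids 1..k ordered by first appearance for determinism
    remap, next_id = {}, 1
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = next_id
            next_id += 1
        labels.append(remap[lab])
    return ClusterAssignment(
        labels=pd.Series(labels, index=m.values.columns, name="cluster"),
        k=int(k), linkage_method=linkage_method, distance_metric=metric,
        silhouette_profile=profile,
    )


def cut_tree_at(m: PsiMatrix, ks: list[int], linkage_method: str = "ward",
                metric: str = "euclidean") -> pd.DataFrame:
    """Cut the same dendrogram at several k (partitions are nested)."""
    _, tree = _linkage_matrix(m, linkage_method, metric)
    out = {}
    for k in ks:
        out[k] = fcluster(tree, t=k, criterion="maxclust")
    return pd.DataFrame(out, index=m.values.columns)


def cluster_enrichment(
    assign: ClusterAssignment,
    labels: Mapping[str, str] | pd.Series,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Fisher exact enrichment of every label in every cluster.

    For cluster c and label L the 2x2 table is
    a = in c with L, b = in c without L, c2 = outside c with L, d = rest.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    missing = set(assign.labels.index) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
    labels = labels.loc[assign.labels.index]

    rows = []
    for cluster in sorted(assign.labels.unique()):
        in_c = assign.labels == cluster
        for lab in sorted(labels.unique()):
            has = labels == lab
            if not has.any():
                logger.warning("label %r has zero samples; skipped", lab)
                continue
            a = int((in_c & has).sum())
            b = int((in_c & ~has).sum())
            c2 = int((~in_c & has).sum())
            d = int((~in_c & ~has).sum())
            _, p = fisher_exact([[a, b], [c2, d]], alternative="two-sided")
            haldane = 0 in (a, b, c2, d)
            if haldane:
                orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c2 + 0.5))
            else:
                orr = (a * d) / (b * c2)
            rows.append({
                "cluster": cluster, "label": lab,
                "a": a, "b": b, "c": c2, "d": d,
                "odds_ratio": orr, "haldane_corrected": haldane, "p": p,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method=adjust)[1]
    return out
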