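"""Gene-set diagnostics for validating subtype calls.

Three complementary tests:

* :func:`hypergeometric_enrichment` — over-representation of a query gene
  list in a named set, upper-tail hypergeometric probability;
* :func:`competitive_gene_set_test` — a camera-style competitive test: is
  the mean per-gene ranking statistic inside the set larger (or smaller)
  than outside, with the variance inflated for inter-gene correlation;
* :func:`ssgsea_score` — a single-sample enrichment score from a weighted
  running-sum over the sample's expression ranking (no cross-sample
  normalization; scores are comparable within one matrix only).

:func:`gsa_summary` ties them to a prediction table: each assigned class is
contrasted against the rest and every gene set tested, giving the familiar
class x set heatmap of signed significance.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataWarning, ValidationError
from .io import NOT_ASSIGNED, GeneSetCollection, validate_expression
from .ntp import benjamini_hochberg

logger = logging.getLogger("ntpkit")

__all__ = [
    "hypergeometric_enrichment",
    "competitive_gene_set_test",
    "ssgsea_score",
    "gsa_summary",
]


def hypergeometric_enrichment(
    query: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]
) -> tuple[float, int]:
    """Upper-tail hypergeometric enrichment of ``query`` in ``gene_set``.

    Returns ``(p, overlap)`` where ``p`` is the probability of drawing at
    least the observed overlap when sampling ``len(query)`` genes from the
    universe containing ``|gene_set & universe|`` successes.  BH adjustment
    across a collection is the caller's job.
    """
    universe_set = set(map(str, universe))
    if not universe_set:
        raise ValidationError("empty universe")
    query_set = set(map(str, query))
    if not query_set:
        raise ValidationError("empty query")
    outside = query_set - universe_set
    if outside:
        raise ValidationError(f"query genes not in universe: {sorted(outside)[:5]}")
    hits = set(map(str, gene_set)) & universe_set
    k = len(query_set & hits)
    M, n, N = len(universe_set), len(hits), len(query_set)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return min(p, 1.0), k


def competitive_gene_set_test(
    stats_per_gene: pd.Series,
    gene_set: Sequence[str],
    inter_gene_correlation: float = 0.01,
) -> tuple[float, float]:
    """Competitive two-sample z-test of a gene set against the rest.

    Compares the mean ranking statistic (e.g. moderated t from a contrast)
    of in-set genes against out-of-set genes.  The variance of the in-set
    mean is inflated by ``VIF = 1 + (m - 1) * rho`` to account for
    inter-gene correlation, which otherwise makes competitive tests wildly
    anti-conservative.  Returns one-sided p-values ``(p_up, p_down)``.
    """
    if inter_gene_correlation < 0:
        raise ValidationError("inter_gene_correlation must be >= 0")
    s = pd.Series(stats_per_gene, dtype=float)
    s.index = s.index.astype(str)
    s = s.dropna()
    in_set = s.index.isin(set(map(str, gene_set)))
    m = int(in_set.sum())
    m2 = int((~in_set).sum())
    if m < 2 or m2 < 2:
        warnings.warn(
            f"gene set overlaps {m} of {len(s)} statistics; skipping (need >= 2 in and out)",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return np.nan, np.nan
    values = s.to_numpy()
    delta = values[in_set].mean() - values[~in_set].mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.5, 0.5
    vif = 1.0 + (m - 1) * inter_gene_correlation
    se = sd * np.sqrt(vif / m + 1.0 / m2)
    z = delta / se
    return float(stats.norm.sf(z)), float(stats.norm.cdf(z))


def ssgsea_score(sample_expr: pd.Series, gene_set: Sequence[str], weight: float = 0.25) -> float:
    """Single-sample enrichment score for one gene set.

    Genes are ranked by expression (descending); walking down the ranking,
    in-set genes add their rank value raised to ``weight`` (normalized so
    in-set steps sum to 1) and out-of-set genes subtract a uniform step.
    The score integrates the running sum, so sets concentrated at the top
    of the ranking score positive and sets at the bottom negative.  At
    ``weight = 0`` the score depends only on the ordering, making it
    invariant to strictly monotone transforms of the expression values.
    """
    if weight < 0:
        raise ValidationError(f"weight must be >= 0, got {weight}")
    expr = pd.Series(sample_expr, dtype=float).dropna()
    expr.index = expr.index.astype(str)
    n = len(expr)
    members = expr.index.isin(set(map(str, gene_set)))
    m = int(members.sum())
    if m < 2:
        raise ValidationError(f"gene set overlaps only {m} genes; need >= 2")
    if m == n:
        raise ValidationError("gene set covers the whole ranking; score undefined")
    values = expr.to_numpy()
    if np.all(values == values[0]):
        warnings.warn("all expression values equal; enrichment score set to 0",
                      DegenerateDataWarning, stacklevel=2)
        return 0.0
    # rank 1 = lowest expression; ties share the average rank
    ranks = stats.rankdata(values, method="average")
    order = np.argsort(-values, kind="mergesort")
    in_set_ordered = members[order]
    rank_ordered = ranks[order]
    inc = np.where(in_set_ordered, np.abs(rank_ordered) ** weight, 0.0)
    inc_total = inc.sum()
    steps = np.where(in_set_ordered, inc / inc_total, -1.0 / (n - m))
    running = np.cumsum(steps)
    return float(running.sum())


def gsa_summary(
    emat: pd.DataFrame,
    preds: pd.DataFrame,
    collection: GeneSetCollection,
    inter_gene_correlation: float = 0.01,
) -> pd.DataFrame:
    """Competitive gene-set tests for every assigned class versus the rest.

    For each class with >= 2 assigned samples, the class-vs-rest contrast
    is computed with :func:`~ntpkit.feature_selection.moderated_t_test` and
    each gene set tested competitively on the moderated t-statistics.
    Two-sided p-values are BH-adjusted across all class x set cells.

    Returns a tidy DataFrame with columns ``class``, ``set``, ``n_genes``,
    ``direction`` (+1 up, -1 down), ``p``, ``adj_p`` and
    ``signed_log10_adj_p``; pivot the latter for a heatmap.
    """
    from .feature_selection import moderated_t_test

    emat = validate_expression(emat)
    if len(collection) == 0:
        return pd.DataFrame(
            columns=["class", "set", "n_genes", "direction", "p", "adj_p", "signed_log10_adj_p"]
        )
    labels = preds["prediction"]
    labels = labels[labels != NOT_ASSIGNED]
    labels = labels[labels.index.isin(emat.columns)]
    counts = labels.value_counts()
    classes = [c for c in dict.fromkeys(labels) if counts[c] >= 2]
    if len(classes) < 2:
        raise ValidationError("need >= 2 assigned classes with >= 2 samples each")

    rows = []
    for cls in classes:
        in_cls = list(labels.index[labels == cls])
        rest = list(labels.index[labels != cls])
        t_stats = moderated_t_test(emat, in_cls, rest)["t_stat"]
        for name in collection:
            p_up, p_down = competitive_gene_set_test(
                t_stats, collection[name], inter_gene_correlation
            )
            if np.isnan(p_up):
                continue
            direction = 1 if p_up <= p_down else -1
            p_two = min(1.0, 2.0 * min(p_up, p_down))
            n_genes = int(t_stats.index.isin(set(collection[name])).sum())
            rows.append({"class": cls, "set": name, "n_genes": n_genes,
                         "direction": direction, "p": p_two})
    out = pd.DataFrame.from_records(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["class", "set", "n_genes", "direction", "p", "adj_p", "signed_log10_adj_p"]
        )
    out["adj_p"] = benjamini_hochberg(np.clip(out["p"], np.finfo(float).tiny, 1.0))
    out["signed_log10_adj_p"] = out["direction"] * (-np.log10(out["adj_p"]))
    return out
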