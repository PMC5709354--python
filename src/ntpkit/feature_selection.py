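"""Derivation of cancer cell-intrinsic subtype marker templates.

Subtype markers selected from bulk tumor cohorts are confounded by the
tumor microenvironment: genes expressed by infiltrating stroma or immune
cells track the mesenchymal-like subtype in tumors but vanish in cell
lines and xenografts.  The template derivation therefore intersects three
filters computed on three different data sources:

1. *candidate markers* — genes with higher expression in each subtype
   versus the rest in a labeled tumor cohort (one-vs-rest moderated-t,
   LFC > 1 and BH-adjusted p < 0.1 by default);
2. *robust markers* — genes that are variable (top-25% 10-90 cross-sample
   inter-percentile range) and expressed (top-25% within-sample in at
   least three samples) across a cell-line panel, which contains no human
   stroma;
3. *intrinsic markers* — genes not lost upon xenografting (tumor-vs-
   xenograft LFC < 2, no p-value threshold).

Differential expression uses gene-wise linear contrasts with
empirical-Bayes variance moderation: gene variances are shrunk toward a
common prior estimated by moment matching on the log sample variances,
which stabilizes the t-statistics when per-group sample counts are small.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .errors import DegenerateDataWarning, DerivationError, ValidationError
from .io import TemplateSet, validate_expression
from .ntp import benjamini_hochberg

logger = logging.getLogger("ntpkit")

__all__ = [
    "moderated_t_test",
    "candidate_markers",
    "robust_intrinsic_filter",
    "intrinsic_filter",
    "derive_template",
    "TemplateSelector",
]


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError(f"trigamma inverse needs y > 0, got {y}")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Matches the mean and variance of log(s2) against the theoretical
    moments of a scaled F distribution.  Returns (prior_df, prior_var), or
    (nan, nan) when matching fails — no excess spread in the log-variances
    (nothing to shrink toward) or a degenerate solution; the caller then
    falls back to the ordinary pooled t.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.nan, np.nan
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.nan, np.nan
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not np.isfinite(d0) or d0 <= 0 or not np.isfinite(s0_2):
        return np.nan, np.nan
    return d0, s0_2


def moderated_t_test(emat: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]) -> pd.DataFrame:
    """Two-group differential expression with moderated t-statistics.

    Per gene: ``lfc`` is mean(A) - mean(B) on log2 data; the pooled
    residual variance (df = n_a + n_b - 2) is shrunk toward an
    empirical-Bayes prior and the moderated t is referred to a
    t-distribution with prior + residual degrees of freedom.  If prior
    estimation fails the ordinary pooled t is used with a warning.

    Returns a DataFrame indexed by gene with columns ``lfc``, ``t_stat``,
    ``p``, ``adj_p`` and ``mean_expr``.  Gene rows with missing values in
    the tested samples are dropped with a logged count.
    """
    emat = validate_expression(emat)
    group_a = [str(s) for s in group_a]
    group_b = [str(s) for s in group_b]
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        missing = [s for s in grp if s not in emat.columns]
        if missing:
            raise ValidationError(f"{name}: samples not in matrix: {missing}")
        if len(grp) < 2:
            raise ValidationError(f"{name} needs >= 2 samples, got {len(grp)}")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")

    sub = emat[group_a + group_b]
    n_drop = int(sub.isna().any(axis=1).sum())
    if n_drop:
        logger.info("moderated_t_test: dropping %d gene rows with missing values", n_drop)
        sub = sub.dropna(axis=0)
    if sub.shape[0] == 0:
        raise ValidationError("no complete gene rows to test")

    A = sub[group_a].to_numpy()
    B = sub[group_b].to_numpy()
    n_a, n_b = len(group_a), len(group_b)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    lfc = mean_a - mean_b
    df_resid = n_a + n_b - 2
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    d0, s0_2 = _fit_variance_prior(s2, df_resid)
    if np.isnan(d0):
        warnings.warn(
            "variance prior estimation failed; falling back to ordinary pooled t",
            DegenerateDataWarning,
            stacklevel=2,
        )
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    t = np.where(se == 0, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "t_stat": t,
            "p": p,
            "adj_p": benjamini_hochberg(p),
            "mean_expr": sub.to_numpy().mean(axis=1),
        },
        index=sub.index,
    )


# ---------------------------------------------------------------------------
# the three filters
# ---------------------------------------------------------------------------

def _check_labels(emat: pd.DataFrame, labels, min_per_class: int = 2) -> pd.Series:
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    labels = labels.astype(str)
    labels.index = labels.index.astype(str)
    missing = [s for s in labels.index if s not in emat.columns]
    if missing:
        raise ValidationError(f"labeled samples not in matrix: {missing}")
    counts = labels.value_counts()
    small = counts[counts < min_per_class]
    if len(small):
        raise ValidationError(
            f"classes with fewer than {min_per_class} samples: {sorted(small.index)}"
        )
    return labels


def candidate_markers(
    emat: pd.DataFrame,
    labels,
    lfc_min: float = 1.0,
    adjp_max: float = 0.1,
) -> dict[str, list[str]]:
    """One-vs-rest candidate subtype markers from a labeled tumor cohort.

    For each class, genes with ``lfc > lfc_min`` and ``adj_p < adjp_max``
    in the class-vs-rest contrast qualify.  A gene qualifying for several
    classes goes to the class with the largest LFC; exact LFC ties are
    excluded with a log message.  Classes are returned in first-appearance
    label order and genes in decreasing LFC.
    """
    emat = validate_expression(emat)
    labels = _check_labels(emat, labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes to contrast")

    best: dict[str, tuple[str, float]] = {}
    dropped_ties: set[str] = set()
    for cls in classes:
        in_cls = list(labels.index[labels == cls])
        rest = list(labels.index[labels != cls])
        de = moderated_t_test(emat, in_cls, rest)
        hits = de[(de["lfc"] > lfc_min) & (de["adj_p"] < adjp_max)]
        for gene, lfc in hits["lfc"].items():
            if gene not in best:
                best[gene] = (cls, lfc)
            elif lfc > best[gene][1]:
                best[gene] = (cls, lfc)
                dropped_ties.discard(gene)
            elif lfc == best[gene][1] and best[gene][0] != cls:
                dropped_ties.add(gene)
    for gene in dropped_ties:
        del best[gene]
        logger.info("candidate_markers: gene %s tied between classes; excluded", gene)

    out: dict[str, list[str]] = {cls: [] for cls in classes}
    for gene, (cls, lfc) in best.items():
        out[cls].append((gene, lfc))
    return {
        cls: [g for g, _ in sorted(pairs, key=lambda x: (-x[1], x[0]))]
        for cls, pairs in out.items()
    }


def robust_intrinsic_filter(
    cellline_emat: pd.DataFrame,
    ipr_top_fraction: float = 0.25,
    expr_top_fraction: float = 0.25,
    min_samples: int = 3,
) -> list[str]:
    """Genes variable and expressed across a stroma-free cell-line panel.

    Keeps genes satisfying both:

    (i)  cross-sample 10th-to-90th inter-percentile range in the top
         ``ipr_top_fraction`` of all genes (strictly above the
         corresponding percentile, linear interpolation);
    (ii) within-sample expression strictly in the sample's top
         ``expr_top_fraction`` in at least ``min_samples`` samples.
    """
    cellline_emat = validate_expression(cellline_emat)
    for name, frac in (("ipr_top_fraction", ipr_top_fraction), ("expr_top_fraction", expr_top_fraction)):
        if not 0 < frac <= 1:
            raise ValidationError(f"{name} must be in (0, 1], got {frac}")
    if min_samples < 1:
        raise ValidationError(f"min_samples must be >= 1, got {min_samples}")
    if cellline_emat.shape[1] < min_samples:
        raise ValidationError(
            f"cell-line panel has {cellline_emat.shape[1]} samples, fewer than "
            f"min_samples={min_samples}"
        )
    n_drop = int(cellline_emat.isna().any(axis=1).sum())
    if n_drop:
        logger.info("robust_intrinsic_filter: dropping %d gene rows with missing values", n_drop)
        cellline_emat = cellline_emat.dropna(axis=0)
    values = cellline_emat.to_numpy()

    q10, q90 = np.percentile(values, [10, 90], axis=1)
    ipr = q90 - q10
    ipr_cut = np.quantile(ipr, 1.0 - ipr_top_fraction)
    pass_ipr = ipr > ipr_cut

    expr_cut = np.quantile(values, 1.0 - expr_top_fraction, axis=0)  # per sample
    n_top = (values > expr_cut[None, :]).sum(axis=1)
    pass_expr = n_top >= min_samples

    kept = [g for g, a, b in zip(cellline_emat.index, pass_ipr, pass_expr) if a and b]
    if not kept:
        warnings.warn(
            "no genes passed the robust filter (degenerate panel?)",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return kept


def intrinsic_filter(
    pcrc_emat: pd.DataFrame,
    pdx_emat: pd.DataFrame,
    lfc_max: float = 2.0,
) -> list[str]:
    """Genes not lost upon xenografting.

    Contrasts the primary-tumor cohort against the xenograft cohort on
    their gene intersection and keeps genes with LFC (tumor minus
    xenograft) strictly below ``lfc_max``; no p-value threshold is
    applied — the filter targets effect size, not significance.
    """
    pcrc_emat = validate_expression(pcrc_emat, context="tumor matrix")
    pdx_emat = validate_expression(pdx_emat, context="xenograft matrix")
    shared = [g for g in pcrc_emat.index if g in set(pdx_emat.index)]
    if not shared:
        raise ValidationError("tumor and xenograft matrices share no genes")
    tumor_cols = [f"t::{s}" for s in pcrc_emat.columns]
    pdx_cols = [f"x::{s}" for s in pdx_emat.columns]
    merged = pd.concat(
        [
            pcrc_emat.loc[shared].set_axis(tumor_cols, axis=1),
            pdx_emat.loc[shared].set_axis(pdx_cols, axis=1),
        ],
        axis=1,
    )
    de = moderated_t_test(merged, tumor_cols, pdx_cols)
    return list(de.index[de["lfc"] < lfc_max])


def derive_template(
    candidates: Mapping[str, Sequence[str]],
    robust: Sequence[str],
    intrinsic: Sequence[str],
) -> tuple[TemplateSet, pd.DataFrame]:
    """Intersect the three filters into the final template.

    Per class, the template members are candidates that also pass the
    robust and intrinsic filters.  The accompanying report records, per
    candidate gene, which class proposed it, which filters it passed and
    the first filter that removed it.  Raises
    :class:`~ntpkit.errors.DerivationError` if any class ends empty.
    """
    robust_set = set(map(str, robust))
    intrinsic_set = set(map(str, intrinsic))
    members: dict[str, list[str]] = {}
    records = []
    for cls, genes in candidates.items():
        kept = []
        for g in map(str, genes):
            in_robust = g in robust_set
            in_intrinsic = g in intrinsic_set
            if in_robust and in_intrinsic:
                final, reason = cls, "kept"
                kept.append(g)
            elif not in_robust:
                final, reason = None, "not_robust"
            else:
                final, reason = None, "not_intrinsic"
            records.append(
                {
                    "gene": g,
                    "candidate_for": cls,
                    "passed_robust": in_robust,
                    "passed_intrinsic": in_intrinsic,
                    "final_class": final,
                    "removal_reason": reason,
                }
            )
        members[str(cls)] = kept
    empty = [cls for cls, genes in members.items() if not genes]
    if empty:
        raise DerivationError(
            f"classes with no genes left after filter intersection: {sorted(empty)}"
        )
    report = pd.DataFrame.from_records(
        records, columns=["gene", "candidate_for", "passed_robust", "passed_intrinsic",
                          "final_class", "removal_reason"]
    )
    return TemplateSet(members), report


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TemplateSelector(BaseEstimator):
    """Supervised selection of a cancer cell-intrinsic subtype template.

    ``fit(X, y)`` takes the labeled tumor cohort in scikit-learn
    orientation (samples x genes) and intersects the candidate filter with
    the robust filter (computed on ``cell_lines``) and the intrinsic
    filter (computed on the ``paired_tumors`` / ``paired_xenografts``
    contrast).  The auxiliary cohorts are genes x samples DataFrames; if
    one is ``None`` the corresponding filter is skipped (all genes pass),
    which is only appropriate for data without stromal confounding.

    Attributes
    ----------
    template_set_ : TemplateSet
        The derived template.
    report_ : DataFrame
        Per-candidate filter provenance.
    candidates_ : dict
        The unfiltered candidate markers per class.
    """

    def __init__(
        self,
        cell_lines: pd.DataFrame | None = None,
        paired_tumors: pd.DataFrame | None = None,
        paired_xenografts: pd.DataFrame | None = None,
        lfc_min: float = 1.0,
        adjp_max: float = 0.1,
        ipr_top_fraction: float = 0.25,
        expr_top_fraction: float = 0.25,
        min_samples: int = 3,
        lfc_max: float = 2.0,
    ):
        self.cell_lines = cell_lines
        self.paired_tumors = paired_tumors
        self.paired_xenografts = paired_xenografts
        self.lfc_min = lfc_min
        self.adjp_max = adjp_max
        self.ipr_top_fraction = ipr_top_fraction
        self.expr_top_fraction = expr_top_fraction
        self.min_samples = min_samples
        self.lfc_max = lfc_max

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a samples x genes DataFrame")
        emat = X.T
        labels = pd.Series(np.asarray(y, dtype=object), index=X.index)
        self.candidates_ = candidate_markers(
            emat, labels, lfc_min=self.lfc_min, adjp_max=self.adjp_max
        )
        all_candidates = [g for genes in self.candidates_.values() for g in genes]
        if self.cell_lines is not None:
            robust = robust_intrinsic_filter(
                self.cell_lines,
                ipr_top_fraction=self.ipr_top_fraction,
                expr_top_fraction=self.expr_top_fraction,
                min_samples=self.min_samples,
            )
        else:
            robust = all_candidates
        if self.paired_tumors is not None and self.paired_xenografts is not None:
            intrinsic = intrinsic_filter(
                self.paired_tumors, self.paired_xenografts, lfc_max=self.lfc_max
            )
        else:
            intrinsic = all_candidates
        self.template_set_, self.report_ = derive_template(self.candidates_, robust, intrinsic)
        self.n_features_in_ = X.shape[1]
        return self
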