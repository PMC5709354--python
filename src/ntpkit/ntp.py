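"""Nearest-template prediction (NTP) with gene-resampling confidence.

The classifier represents each subtype as an indicator vector over a set of
disjoint marker genes (the *template*).  A sample is assigned to the class
whose indicator is most similar — cosine similarity on gene-wise centered
and scaled expression, which equals Pearson correlation — to the sample's
profile over the template genes.

Confidence is estimated by gene resampling: random gene sets of the same
size and per-class partition are drawn from all genes of the input matrix,
and the maximum similarity over classes is recorded for each draw.  The
resampling p-value is the fraction of null draws at least as similar as the
observed best class (with the standard +1 correction, so p is never zero).
p-values are Benjamini-Hochberg adjusted across samples and samples with
FDR above ``alpha`` are *not assigned* — their best fit is no better than
random gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

from .errors import (
    CoverageError,
    SmallCohortWarning,
    UndefinedStatisticError,
    ValidationError,
)
from .io import NOT_ASSIGNED, TemplateSet, validate_expression
from .preprocess import row_center_scale

logger = logging.getLogger("ntpkit")

__all__ = [
    "cosine_similarity",
    "TemplateMatrix",
    "build_template_matrix",
    "benjamini_hochberg",
    "ntp_classify",
    "NTPClassifier",
]

#: Below this sample count, cross-sample standardization is warned about.
SMALL_COHORT_N = 40


def cosine_similarity(x, t) -> float:
    """Cosine of the angle between two vectors: dot(x, t) / (|x| |t|)."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.ndim != 1 or t.ndim != 1 or x.shape != t.shape:
        raise ValidationError(f"vectors must be 1-d of equal length, got {x.shape} and {t.shape}")
    if x.size < 2:
        raise ValidationError("vectors must have length >= 2")
    nx = np.linalg.norm(x)
    nt = np.linalg.norm(t)
    if nx == 0.0 or nt == 0.0:
        raise UndefinedStatisticError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(x, t) / (nx * nt))


@dataclass(frozen=True)
class TemplateMatrix:
    """Template genes aligned to a data matrix, as a gene x class indicator.

    Rows are the template genes present in the data (in data row order);
    each row has exactly one 1 (disjoint class membership).
    """

    genes: tuple
    classes: tuple
    indicators: np.ndarray  # (n_genes, n_classes) of 0/1 floats

    @property
    def class_counts(self) -> np.ndarray:
        return self.indicators.sum(axis=0).astype(int)


def build_template_matrix(templates: TemplateSet, emat, min_fraction: float = 0.5) -> TemplateMatrix:
    """Restrict a template to the genes present in ``emat``.

    ``emat`` may be a DataFrame or any iterable of gene ids.  Classes whose
    fraction of matched genes falls below ``min_fraction`` raise a
    :class:`CoverageError`; partially matched classes log a warning.
    Row order follows the data.
    """
    if not 0 < min_fraction <= 1:
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    gene_order = list(emat.index) if isinstance(emat, pd.DataFrame) else list(emat)
    present = set(gene_order)
    for cls in templates.classes:
        genes = templates[cls]
        n_found = sum(g in present for g in genes)
        frac = n_found / len(genes)
        if frac < min_fraction:
            raise CoverageError(
                f"class {cls!r}: only {n_found}/{len(genes)} template genes in data "
                f"({frac:.0%} < {min_fraction:.0%})"
            )
        if n_found < len(genes):
            warnings.warn(f"{cls}: {n_found}/{len(genes)} genes matched", stacklevel=2)
    template_genes = set(templates.genes)
    kept = tuple(g for g in gene_order if g in template_genes)
    class_index = {c: j for j, c in enumerate(templates.classes)}
    indicators = np.zeros((len(kept), len(templates.classes)))
    for i, g in enumerate(kept):
        indicators[i, class_index[templates.class_of(g)]] = 1.0
    return TemplateMatrix(genes=kept, classes=templates.classes, indicators=indicators)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to input
    order; the output is elementwise >= the input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _max_null_similarity(X, idx, T, tnorm):
    """Maximum over classes of null cosine similarities.

    ``idx`` is either (draws, k) — draws shared across samples — or
    (draws, n_samples, k) — independent draws per sample.  Returns an array
    (draws, n_samples).
    """
    if idx.ndim == 2:
        xs = X[idx]  # (r, k, S)
        num = np.einsum("rks,kc->rsc", xs, T)
        sq = np.einsum("rks,rks->rs", xs, xs)
    else:
        xs = X[idx, np.arange(X.shape[1])[None, :, None]]  # (r, S, k)
        num = np.einsum("rsk,kc->rsc", xs, T)
        sq = np.einsum("rsk,rsk->rs", xs, xs)
    xnorm = np.sqrt(sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = num / (xnorm[..., None] * tnorm[None, None, :])
    # zero-norm null profiles have undefined similarity; they cannot win
    sims = np.where(np.isfinite(sims), sims, -np.inf)
    return sims.max(axis=2)


def ntp_classify(
    emat: pd.DataFrame,
    templates: TemplateSet,
    n_resample: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 7,
    do_row_scale: bool = True,
    min_fraction: float = 0.5,
    share_draws: bool = False,
) -> pd.DataFrame:
    """Classify samples by nearest template with resampling confidence.

    Parameters
    ----------
    emat : DataFrame
        Genes x samples log-scale expression.  Gene rows with missing
        values are dropped with a logged count.
    templates : TemplateSet
        Disjoint per-class marker lists.
    n_resample : int
        Number of random gene sets per sample for the null distribution.
    alpha : float
        FDR threshold; samples with adjusted p above it are not assigned.
    seed : int or None
        Seed for the resampling generator; fixed seeds give identical
        tables.
    do_row_scale : bool
        Gene-wise center and scale before computing similarities (requires
        >= 2 samples); with scaling, cosine similarity equals Pearson
        correlation with the class indicator.
    share_draws : bool
        Reuse one set of null gene draws for every sample (faster; the
        default draws independently per sample).

    Returns
    -------
    DataFrame indexed by sample with columns ``prediction``, one
    similarity column per class, ``p_value``, ``fdr`` and ``tie_flag``.
    """
    if n_resample < 1:
        raise ValidationError(f"n_resample must be >= 1, got {n_resample}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    emat = validate_expression(emat)

    n_missing_rows = int(emat.isna().any(axis=1).sum())
    if n_missing_rows:
        logger.info("dropping %d gene rows with missing values", n_missing_rows)
        emat = emat.dropna(axis=0)
        if emat.shape[0] == 0:
            raise ValidationError("no complete gene rows left after dropping missing values")

    n_samples = emat.shape[1]
    if do_row_scale:
        if n_samples < 2:
            raise ValidationError(
                "row scaling needs >= 2 samples; pass do_row_scale=False for single samples"
            )
        if n_samples < SMALL_COHORT_N:
            warnings.warn(
                f"only {n_samples} samples: cross-sample centering/scaling from fewer than "
                f"~{SMALL_COHORT_N} samples introduces prediction uncertainty",
                SmallCohortWarning,
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate rows already logged upstream
            emat = row_center_scale(emat, center=True, scale=True)

    tm = build_template_matrix(templates, emat, min_fraction=min_fraction)
    X = emat.to_numpy()  # (n_genes, S)
    n_genes = X.shape[0]
    k = len(tm.genes)
    if k > n_genes:
        raise ValidationError("template larger than the gene universe")
    T = tm.indicators
    tnorm = np.linalg.norm(T, axis=0)

    gene_pos = {g: i for i, g in enumerate(emat.index)}
    tpl_idx = np.array([gene_pos[g] for g in tm.genes])
    Xt = X[tpl_idx]  # (k, S)
    xnorm = np.linalg.norm(Xt, axis=0)
    if np.any(xnorm == 0):
        bad = [emat.columns[j] for j in np.flatnonzero(xnorm == 0)]
        raise UndefinedStatisticError(
            f"zero-norm template-gene profile for samples {bad}; similarity undefined"
        )
    sims = (Xt.T @ T) / (xnorm[:, None] * tnorm[None, :])  # (S, C)

    best = sims.max(axis=1)
    is_best = sims == best[:, None]
    tie_flag = is_best.sum(axis=1) > 1
    pred_idx = is_best.argmax(axis=1)  # earliest class in template order wins ties
    if tie_flag.any():
        warnings.warn(
            f"{int(tie_flag.sum())} samples with tied best similarity; "
            "assigned to the earliest class in template order",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    ge = np.zeros(n_samples, dtype=np.int64)
    if share_draws:
        budget = max(1, int(3e7) // max(n_genes, 1))
    else:
        budget = max(1, int(3e7) // max(n_samples * n_genes, 1))
    done = 0
    while done < n_resample:
        r = min(budget, n_resample - done)
        if share_draws:
            u = rng.random((r, n_genes))
        else:
            u = rng.random((r, n_samples, n_genes))
        if k < n_genes:
            idx = np.argpartition(u, k, axis=-1)[..., :k]
        else:
            idx = np.argsort(u, axis=-1)
        null_max = _max_null_similarity(X, idx, T, tnorm)
        ge += (null_max >= best[None, :]).sum(axis=0)
        done += r
    p = (1 + ge) / (n_resample + 1)
    fdr = benjamini_hochberg(p)

    prediction = np.array([tm.classes[j] for j in pred_idx], dtype=object)
    prediction[fdr > alpha] = NOT_ASSIGNED

    out = pd.DataFrame({"prediction": prediction}, index=emat.columns)
    for j, cls in enumerate(tm.classes):
        out[cls] = sims[:, j]
    out["p_value"] = p
    out["fdr"] = fdr
    out["tie_flag"] = tie_flag
    return out


class NTPClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn interface to nearest-template prediction.

    Unlike most classifiers the parameters are not learned from training
    data — they *are* the template.  ``fit`` validates the template against
    the supplied feature space; ``predict`` classifies new samples, using
    the prediction cohort itself for gene standardization and for the
    resampling gene universe.

    Parameters
    ----------
    templates : TemplateSet
        Per-class marker gene lists.
    n_resample, alpha, row_scale, min_fraction, share_draws, random_state
        See :func:`ntp_classify`.

    Attributes
    ----------
    classes_ : ndarray
        Template classes plus the not-assigned label.
    genes_ : tuple
        Template genes matched in the fitted feature space.

    Notes
    -----
    ``X`` follows the scikit-learn orientation (samples x genes, genes as
    columns), the transpose of the package's expression-matrix convention.
    """

    def __init__(
        self,
        templates: TemplateSet | None = None,
        n_resample: int = 1000,
        alpha: float = 0.05,
        row_scale: bool = True,
        min_fraction: float = 0.5,
        share_draws: bool = False,
        random_state: int | None = 7,
    ):
        self.templates = templates
        self.n_resample = n_resample
        self.alpha = alpha
        self.row_scale = row_scale
        self.min_fraction = min_fraction
        self.share_draws = share_draws
        self.random_state = random_state

    def _as_emat(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError(
                "X must be a samples x genes DataFrame with gene ids as columns"
            )
        return X.T

    def fit(self, X, y=None):
        """Validate the template against the feature space of ``X``."""
        if self.templates is None:
            raise ValidationError("templates must be provided")
        emat = self._as_emat(X)
        tm = build_template_matrix(self.templates, emat, min_fraction=self.min_fraction)
        self.genes_ = tm.genes
        self.classes_ = np.array(list(tm.classes) + [NOT_ASSIGNED], dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_table(self, X) -> pd.DataFrame:
        """Full prediction table (class, similarities, p, FDR, tie flag)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "classes_")
        return ntp_classify(
            self._as_emat(X),
            self.templates,
            n_resample=self.n_resample,
            alpha=self.alpha,
            seed=self.random_state,
            do_row_scale=self.row_scale,
            min_fraction=self.min_fraction,
            share_draws=self.share_draws,
        )

    def predict(self, X) -> np.ndarray:
        return self.predict_table(X)["prediction"].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        """Per-class cosine similarities, samples x classes."""
        table = self.predict_table(X)
        return table[list(self.templates.classes)].to_numpy()

    def score(self, X, y) -> float:
        """Overall accuracy versus reference labels, not-assigned excluded."""
        from .evaluate import overall_accuracy

        return overall_accuracy(self.predict(X), np.asarray(y)).accuracy
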