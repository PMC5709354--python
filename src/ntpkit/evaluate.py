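"""Evaluation experiments: accuracy, concordance, stability, cycle consistency.

Accuracy throughout is *overall accuracy*: classification agreements
divided by the number of cases, with not-assigned samples excluded from
both numerator and denominator.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DerivationError, UndefinedStatisticError, ValidationError
from .io import NOT_ASSIGNED, TemplateSet, validate_expression
from .ntp import ntp_classify

logger = logging.getLogger("ntpkit")

__all__ = [
    "AccuracyResult",
    "overall_accuracy",
    "binomial_accuracy_test",
    "concordance",
    "consistent_assignment_fraction",
    "subset_stability",
    "cycle_consistency",
]


@dataclass
class AccuracyResult:
    accuracy: float
    n_assigned: int
    n_total: int
    confusion: pd.DataFrame          # rows = reference, columns = predicted (assigned only)
    class_stats: pd.DataFrame        # per class: sensitivity, specificity (assigned only)


def _as_label_array(labels, name: str) -> np.ndarray:
    arr = np.asarray(pd.Series(labels).astype(str))
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-dimensional")
    return arr


def overall_accuracy(pred, ref) -> AccuracyResult:
    """Accuracy over assigned samples, with confusion and per-class stats.

    Sensitivity for class c is TP / (reference c among assigned);
    specificity is TN / (reference non-c among assigned).
    """
    pred = _as_label_array(pred, "pred")
    ref = _as_label_array(ref, "ref")
    if pred.shape != ref.shape:
        raise ValidationError(f"length mismatch: {pred.shape[0]} predictions, {ref.shape[0]} references")
    assigned = pred != NOT_ASSIGNED
    n_assigned = int(assigned.sum())
    if n_assigned == 0:
        raise UndefinedStatisticError("accuracy undefined: no assigned predictions")
    p, r = pred[assigned], ref[assigned]
    accuracy = float((p == r).mean())
    classes = sorted(set(r) | set(p))
    confusion = pd.crosstab(
        pd.Series(r, name="reference"), pd.Series(p, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    rows = {}
    for cls in classes:
        tp = int(((p == cls) & (r == cls)).sum())
        fn = int(((p != cls) & (r == cls)).sum())
        fp = int(((p == cls) & (r != cls)).sum())
        tn = int(((p != cls) & (r != cls)).sum())
        rows[cls] = {
            "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
            "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        }
    return AccuracyResult(
        accuracy=accuracy,
        n_assigned=n_assigned,
        n_total=int(pred.shape[0]),
        confusion=confusion,
        class_stats=pd.DataFrame.from_dict(rows, orient="index"),
    )


def binomial_accuracy_test(
    n_correct: int, n_total: int, no_information_rate: float
) -> tuple[float, tuple[float, float]]:
    """Exact one-sided binomial test of accuracy against the NIR.

    The no-information rate is the accuracy of always predicting the
    majority class.  Returns the p-value for observing at least
    ``n_correct`` successes under the NIR, and the exact (Clopper-Pearson)
    95% confidence interval for the accuracy.
    """
    if not 0 < no_information_rate < 1:
        raise ValidationError(f"no_information_rate must be in (0, 1), got {no_information_rate}")
    if n_total < 1 or not 0 <= n_correct <= n_total:
        raise ValidationError(f"need 0 <= n_correct <= n_total, got {n_correct}/{n_total}")
    test = stats.binomtest(n_correct, n_total, no_information_rate, alternative="greater")
    ci = stats.binomtest(n_correct, n_total).proportion_ci(confidence_level=0.95, method="exact")
    return float(test.pvalue), (float(ci.low), float(ci.high))


def concordance(pred_a, pred_b) -> float:
    """Agreement fraction over samples assigned in both prediction vectors."""
    a = _as_label_array(pred_a, "pred_a")
    b = _as_label_array(pred_b, "pred_b")
    if a.shape != b.shape:
        raise ValidationError("prediction vectors differ in length")
    both = (a != NOT_ASSIGNED) & (b != NOT_ASSIGNED)
    if not both.any():
        raise UndefinedStatisticError("concordance undefined: no jointly assigned samples")
    return float((a[both] == b[both]).mean())


def consistent_assignment_fraction(predictions: Sequence) -> float:
    """Fraction of samples assigned to one single class by every vector."""
    arrays = [_as_label_array(p, "predictions") for p in predictions]
    if len(arrays) < 2:
        raise ValidationError("need >= 2 prediction vectors")
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValidationError("prediction vectors differ in length")
    stacked = np.vstack(arrays)
    assigned_everywhere = (stacked != NOT_ASSIGNED).all(axis=0)
    same_class = (stacked == stacked[0]).all(axis=0)
    return float((assigned_everywhere & same_class).mean())


def subset_stability(
    emat: pd.DataFrame,
    templates: TemplateSet,
    ref,
    sizes: Sequence[int] = tuple(range(10, 81, 10)),
    reps: int = 100,
    seed: int | None = None,
    n_resample: int = 1000,
    alpha: float = 0.05,
    rescale_within_subset: bool = True,
) -> pd.DataFrame:
    """Accuracy distributions on random sample subsets of varying size.

    For each size and repetition a subset is drawn uniformly without
    replacement (ignoring class balance), expression is re-centered and
    re-scaled *within the subset*, samples are classified and overall
    accuracy against the reference recorded.  The within-subset scaling is
    what makes small cohorts unstable: the standardization statistics
    depend on the subset's chance class composition.

    Returns a long DataFrame with columns ``size``, ``rep``, ``accuracy``
    (NaN when a repetition assigned no samples) and ``assigned_fraction``.
    """
    emat = validate_expression(emat)
    ref = pd.Series(ref).astype(str)
    ref.index = ref.index.astype(str)
    missing = [s for s in emat.columns if s not in ref.index]
    if missing:
        raise ValidationError(f"reference labels missing for samples: {missing[:5]}")
    sizes = [int(s) for s in sizes]
    if min(sizes) < 2:
        raise ValidationError("subset sizes must be >= 2 (scaling undefined below that)")
    if max(sizes) > emat.shape[1]:
        raise ValidationError(
            f"largest subset size {max(sizes)} exceeds cohort size {emat.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    columns = np.asarray(emat.columns)
    import warnings as _warnings

    for size in sizes:
        for rep in range(reps):
            chosen = rng.choice(columns, size=size, replace=False)
            sub = emat[list(chosen)]
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                preds = ntp_classify(
                    sub,
                    templates,
                    n_resample=n_resample,
                    alpha=alpha,
                    seed=int(rng.integers(2**31 - 1)),
                    do_row_scale=rescale_within_subset,
                    share_draws=True,
                )
            pred = preds["prediction"].to_numpy()
            truth = ref.loc[list(chosen)].to_numpy()
            assigned = pred != NOT_ASSIGNED
            if assigned.any():
                acc = float((pred[assigned] == truth[assigned]).mean())
            else:
                acc = np.nan
            rows.append(
                {"size": size, "rep": rep, "accuracy": acc,
                 "assigned_fraction": float(assigned.mean())}
            )
    return pd.DataFrame.from_records(rows)


def cycle_consistency(
    emat_a: pd.DataFrame,
    labels_a,
    emat_b: pd.DataFrame,
    ref_b,
    exclude_genes: Sequence[str] = (),
    lfc_min: float = 1.0,
    adjp_max: float = 0.1,
    n_resample: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 7,
) -> tuple[AccuracyResult, TemplateSet]:
    """Derive a fresh template from cohort A and classify cohort B with it.

    The subtype calls on cohort A (e.g. xenografts classified with the
    original template) serve as training labels for a new candidate-marker
    template; ``exclude_genes`` — typically the original template — are
    removed from eligibility before the differential-expression step, so
    the new classifier shares no features with the one that produced the
    labels.  Cohort B is then classified and scored against its reference.
    """
    from .feature_selection import candidate_markers

    emat_a = validate_expression(emat_a, context="cohort A")
    labels_a = pd.Series(labels_a).astype(str)
    labels_a.index = labels_a.index.astype(str)
    labels_a = labels_a[labels_a != NOT_ASSIGNED]
    counts = labels_a.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError("labels_a needs >= 2 classes with >= 2 samples each")
    labels_a = labels_a[labels_a.map(counts) >= 2]

    excluded = set(map(str, exclude_genes))
    eligible = [g for g in emat_a.index if g not in excluded]
    if not eligible:
        raise ValidationError("all genes excluded from eligibility")
    candidates = candidate_markers(
        emat_a.loc[eligible], labels_a, lfc_min=lfc_min, adjp_max=adjp_max
    )
    empty = [cls for cls, genes in candidates.items() if not genes]
    if empty:
        raise DerivationError(f"no template genes left for classes {sorted(empty)} after exclusion")
    new_template = TemplateSet(candidates)
    preds = ntp_classify(
        validate_expression(emat_b, context="cohort B"),
        new_template,
        n_resample=n_resample,
        alpha=alpha,
        seed=seed,
    )
    ref_b = pd.Series(ref_b).astype(str)
    ref_b.index = ref_b.index.astype(str)
    result = overall_accuracy(
        preds["prediction"].to_numpy(), ref_b.loc[preds.index].to_numpy()
    )
    return result, new_template
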