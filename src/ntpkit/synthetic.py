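"""Synthetic labeled expression cohorts with planted subtype structure.

The generator emulates the three data sources the template derivation
needs, on log2 scale:

* a *tumor cohort*: per-class marker blocks plus a stromal signature whose
  strength scales with a per-sample stromal fraction (tumor purity varies);
* a *cell-line / model panel*: the same class structure but no stromal
  signal (models contain no human stroma);
* a *paired tumor/xenograft* pair: two cohorts sharing baseline gene means
  and marker effects, stroma present only in the tumors — the contrast used
  to strip stroma-derived markers.

The model is Gaussian on the log scale: baseline per-gene means are drawn
from Normal(7, 1.5), class markers add ``marker_lfc`` for samples of their
class, stromal genes add ``stromal_lfc`` scaled by the sample's relative
stromal fraction, and i.i.d. Normal(0, noise_sd) noise is added.  The
per-sample stromal multiplier is Uniform(0.3, 1) divided by its mean, so
``stromal_lfc`` is the *expected cohort-level* tumor-versus-model log2
fold change while individual tumors remain heterogeneous.  A count mode
(Poisson with log-normal rates) is available where read-count semantics
matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import TemplateSet

__all__ = ["SyntheticTruth", "simulate_cohort", "simulate_model_pair"]

_BASELINE_MEAN = 7.0
_BASELINE_SD = 1.5
_STROMAL_FRACTION_LOW = 0.3
_STROMAL_FRACTION_HIGH = 1.0
_STROMAL_FRACTION_MEAN = (_STROMAL_FRACTION_LOW + _STROMAL_FRACTION_HIGH) / 2.0


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    labels: pd.Series                       # sample id -> class
    marker_map: dict[str, list[str]]        # class -> planted marker genes
    stromal_genes: list[str]
    params: dict = field(default_factory=dict)

    @property
    def template(self) -> TemplateSet:
        """The planted markers as a classification template."""
        return TemplateSet(self.marker_map)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.to_dict(),
            "marker_map": self.marker_map,
            "stromal_genes": self.stromal_genes,
            "params": self.params,
        }


def _class_labels(n_samples: int, k_classes: int) -> list[int]:
    """Equal class proportions up to rounding, interleaved."""
    return [i % k_classes for i in range(n_samples)]


def _signal_matrix(
    gene_means: np.ndarray,
    label_idx: np.ndarray,
    marker_idx: list[np.ndarray],
    stromal_idx: np.ndarray,
    marker_lfc: float,
    stromal_lfc: float,
    stromal_present: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    n_genes = gene_means.size
    n_samples = label_idx.size
    signal = np.tile(gene_means[:, None], (1, n_samples))
    for c, idx in enumerate(marker_idx):
        signal[np.ix_(idx, np.flatnonzero(label_idx == c))] += marker_lfc
    if stromal_present and stromal_idx.size:
        fractions = rng.uniform(_STROMAL_FRACTION_LOW, _STROMAL_FRACTION_HIGH, size=n_samples)
        signal[stromal_idx, :] += stromal_lfc * (fractions / _STROMAL_FRACTION_MEAN)[None, :]
    return signal


def simulate_cohort(
    n_samples: int = 120,
    n_genes: int = 2000,
    k_classes: int = 4,
    markers_per_class: int = 50,
    marker_lfc: float = 2.0,
    noise_sd: float = 1.0,
    n_stromal: int = 100,
    stromal_lfc: float = 3.0,
    stromal_present: bool = True,
    seed: int | None = None,
    counts: bool = False,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one labeled cohort with planted markers and stroma.

    Returns ``(emat, truth)`` where ``emat`` is genes x samples log2
    expression (or Poisson counts if ``counts=True``) and ``truth`` records
    labels, the marker map, the stromal gene list and all parameters.
    Identical seeds give bit-identical outputs.
    """
    if n_samples < 1 or n_genes < 1 or k_classes < 1 or markers_per_class < 0:
        raise ValidationError("sizes must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    planted = k_classes * markers_per_class + n_stromal
    if planted > n_genes:
        raise ValidationError(
            f"gene budget infeasible: {k_classes} x {markers_per_class} markers + "
            f"{n_stromal} stromal = {planted} > n_genes = {n_genes}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    classes = [f"C{c + 1}" for c in range(k_classes)]

    marker_idx = [
        np.arange(c * markers_per_class, (c + 1) * markers_per_class) for c in range(k_classes)
    ]
    stromal_idx = np.arange(k_classes * markers_per_class, planted)
    label_idx = np.asarray(_class_labels(n_samples, k_classes))

    gene_means = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_genes)
    signal = _signal_matrix(
        gene_means, label_idx, marker_idx, stromal_idx,
        marker_lfc, stromal_lfc, stromal_present, rng,
    )
    values = signal + rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else signal
    if counts:
        values = rng.poisson(np.exp2(np.clip(values, None, 30.0))).astype(float)
    emat = pd.DataFrame(values, index=genes, columns=samples)
    truth = SyntheticTruth(
        labels=pd.Series([classes[c] for c in label_idx], index=samples, name="label"),
        marker_map={classes[c]: [genes[i] for i in marker_idx[c]] for c in range(k_classes)},
        stromal_genes=[genes[i] for i in stromal_idx],
        params={
            "n_samples": n_samples, "n_genes": n_genes, "k_classes": k_classes,
            "markers_per_class": markers_per_class, "marker_lfc": marker_lfc,
            "noise_sd": noise_sd, "n_stromal": n_stromal, "stromal_lfc": stromal_lfc,
            "stromal_present": stromal_present, "seed": seed, "counts": counts,
        },
    )
    return emat, truth


def simulate_model_pair(
    n_samples: int = 120,
    n_genes: int = 2000,
    k_classes: int = 4,
    markers_per_class: int = 50,
    marker_lfc: float = 2.0,
    noise_sd: float = 1.0,
    n_stromal: int = 100,
    stromal_lfc: float = 3.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a paired tumor/xenograft contrast.

    Both cohorts share baseline gene means and marker effects; stromal
    genes carry the stromal elevation only in the tumor cohort (xenografts
    lose human stroma).  Sample labels are drawn independently per cohort;
    tumor samples are prefixed ``T`` and xenografts ``X``.  The returned
    truth covers both cohorts' samples.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    planted = k_classes * markers_per_class + n_stromal
    if planted > n_genes:
        raise ValidationError(
            f"gene budget infeasible: {planted} planted genes > n_genes = {n_genes}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    classes = [f"C{c + 1}" for c in range(k_classes)]
    marker_idx = [
        np.arange(c * markers_per_class, (c + 1) * markers_per_class) for c in range(k_classes)
    ]
    stromal_idx = np.arange(k_classes * markers_per_class, planted)
    gene_means = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_genes)

    cohorts = {}
    labels = {}
    for prefix, stromal_present in (("T", True), ("X", False)):
        label_idx = rng.permutation(np.asarray(_class_labels(n_samples, k_classes)))
        signal = _signal_matrix(
            gene_means, label_idx, marker_idx, stromal_idx,
            marker_lfc, stromal_lfc, stromal_present, rng,
        )
        values = signal + rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else signal
        samples = [f"{prefix}{i:04d}" for i in range(n_samples)]
        cohorts[prefix] = pd.DataFrame(values, index=genes, columns=samples)
        labels[prefix] = pd.Series([classes[c] for c in label_idx], index=samples)

    truth = SyntheticTruth(
        labels=pd.concat([labels["T"], labels["X"]]).rename("label"),
        marker_map={classes[c]: [genes[i] for i in marker_idx[c]] for c in range(k_classes)},
        stromal_genes=[genes[i] for i in stromal_idx],
        params={
            "n_samples": n_samples, "n_genes": n_genes, "k_classes": k_classes,
            "markers_per_class": markers_per_class, "marker_lfc": marker_lfc,
            "noise_sd": noise_sd, "n_stromal": n_stromal, "stromal_lfc": stromal_lfc,
            "seed": seed,
        },
    )
    return cohorts["T"], cohorts["X"], truth
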