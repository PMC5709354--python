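"""Containers and readers/writers for expression subtyping.

The universal currency of the package is the *expression matrix*: a pandas
``DataFrame`` with gene identifiers as the row index and sample identifiers
as columns, holding numeric expression values (log2 scale by convention
after preprocessing).  Gene identifiers are opaque strings compared by
exact, case-sensitive equality; no symbol/Entrez mapping is attempted.

Supported formats
-----------------
* expression: tab-separated text with a header row of sample ids and gene
  ids in the first column, or GCT 1.2;
* templates: two-column table (gene, class), header auto-detected;
* gene sets: GMT (name, description, genes...);
* predictions: tab-separated table written by :func:`write_predictions`.

Missing values are permitted on input; downstream operations that cannot
tolerate them drop incomplete gene rows with a logged count rather than
imputing.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("ntpkit")

#: Serialized label for samples whose best-template fit is not significantly
#: better than random gene sets at the chosen FDR.
NOT_ASSIGNED = "NA"

__all__ = [
    "NOT_ASSIGNED",
    "TemplateSet",
    "GeneSetCollection",
    "validate_expression",
    "read_expression",
    "write_expression",
    "read_template",
    "write_template",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
    "write_predictions",
    "read_predictions",
]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(emat: pd.DataFrame, *, context: str = "expression matrix") -> pd.DataFrame:
    """Validate and coerce a genes x samples expression matrix.

    Enforces unique gene and sample identifiers and numeric values; infinite
    values are converted to missing with a logged count.  Returns a float
    copy with string identifiers.
    """
    if not isinstance(emat, pd.DataFrame):
        raise ValidationError(f"{context}: expected a pandas DataFrame, got {type(emat).__name__}")
    if emat.shape[0] == 0 or emat.shape[1] == 0:
        raise ValidationError(f"{context}: matrix is empty (shape {emat.shape})")
    out = emat.copy()
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    dup_genes = out.index[out.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValidationError(f"{context}: duplicate gene ids: {sorted(dup_genes)}")
    dup_samples = out.columns[out.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValidationError(f"{context}: duplicate sample ids: {sorted(dup_samples)}")
    try:
        values = out.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{context}: non-numeric values present: {exc}") from exc
    n_inf = int(np.isinf(values).sum())
    if n_inf:
        logger.info("%s: %d infinite values set to missing", context, n_inf)
        values = np.where(np.isinf(values), np.nan, values)
    return pd.DataFrame(values, index=out.index, columns=out.columns)


def read_expression(path, format: str = "auto") -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or GCT 1.2.

    Non-numeric cells become missing with a logged count; duplicate gene ids
    are rejected.
    """
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValidationError(f"unknown expression format {format!r}; expected 'tsv' or 'gct'")

    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: line 1: expected GCT version tag '#1.2', got {version!r}")
            dim_line = fh.readline()
            fields = dim_line.split()
            if len(fields) != 2 or not all(f.lstrip("-").isdigit() for f in fields):
                raise ParseError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>', got {dim_line!r}")
            n_genes, n_samples = (int(f) for f in fields)
            try:
                raw = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
            except pd.errors.EmptyDataError as exc:
                raise ParseError(f"{path}: line 3: missing GCT header row") from exc
        if raw.shape[1] < 1:
            raise ParseError(f"{path}: line 3: GCT header lacks a Description column")
        raw = raw.drop(columns=raw.columns[0])  # Description column
        if raw.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: dimension line declares {n_genes} x {n_samples} "
                f"but table is {raw.shape[0]} x {raw.shape[1]}"
            )
    else:
        try:
            raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: line 1: empty file or missing header row") from exc
        if raw.shape[1] == 0:
            raise ParseError(f"{path}: line 1: header row has no sample columns")

    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene ids: {sorted(dup)}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    n_coerced = int(numeric.isna().sum().sum()) - int(raw.isna().sum().sum())
    if n_coerced:
        logger.info("%s: %d non-numeric cells set to missing", path, n_coerced)
    out = validate_expression(numeric, context=str(path))
    out.index.name = None
    out.columns.name = None
    return out


def write_expression(emat: pd.DataFrame, path, format: str = "auto") -> None:
    """Write a genes x samples matrix as TSV or GCT 1.2."""
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    emat = validate_expression(emat)
    if format == "tsv":
        emat.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{emat.shape[0]}\t{emat.shape[1]}\n")
            out = emat.copy()
            out.insert(0, "Description", emat.index)
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValidationError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

class TemplateSet:
    """Per-class marker gene lists — the parameters of the classifier.

    Classes are kept in the order supplied (first appearance); every class
    has at least one gene and a gene belongs to at most one class.  Both
    invariants are enforced at construction, so no reachable instance
    violates them.
    """

    def __init__(self, members: Mapping[str, Sequence[str]]):
        if not members:
            raise ValidationError("template has no classes")
        cleaned: dict[str, tuple[str, ...]] = {}
        owner: dict[str, str] = {}
        for cls, genes in members.items():
            cls = str(cls)
            if cls in cleaned:
                raise ValidationError(f"class {cls!r} listed twice")
            kept: list[str] = []
            for g in genes:
                g = str(g)
                if g in owner:
                    if owner[g] == cls:
                        continue  # duplicate within the class; keep first
                    raise ValidationError(
                        f"gene {g!r} assigned to both class {owner[g]!r} and class {cls!r}"
                    )
                owner[g] = cls
                kept.append(g)
            if not kept:
                raise ValidationError(f"class {cls!r} has no genes")
            cleaned[cls] = tuple(kept)
        if len(cleaned) < 1:
            raise ValidationError("template has no classes")
        self._members = cleaned
        self._owner = owner

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self._members)

    @property
    def members(self) -> dict[str, tuple[str, ...]]:
        return dict(self._members)

    @property
    def genes(self) -> tuple[str, ...]:
        """All template genes, grouped by class in class order."""
        return tuple(g for cls in self._members for g in self._members[cls])

    def class_of(self, gene: str) -> str | None:
        return self._owner.get(str(gene))

    @property
    def n_genes(self) -> int:
        return len(self._owner)

    def __getitem__(self, cls: str) -> tuple[str, ...]:
        return self._members[cls]

    def __iter__(self):
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __eq__(self, other) -> bool:
        return isinstance(other, TemplateSet) and self._members == other._members

    def __repr__(self) -> str:
        sizes = ", ".join(f"{c}: {len(g)}" for c, g in self._members.items())
        return f"TemplateSet({sizes})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.genes), "class": [self._owner[g] for g in self.genes]}
        )


_TEMPLATE_HEADER_HINTS = {
    "gene", "gene_id", "geneid", "id", "feature", "probe", "probe_id", "symbol",
    "class", "label", "subtype", "template", "group",
}


def read_template(path) -> TemplateSet:
    """Read a two-column (gene, class) table; header auto-detected."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and (rows[0][0].lower() in _TEMPLATE_HEADER_HINTS
                 or rows[0][1].lower() in _TEMPLATE_HEADER_HINTS):
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{path}: no template rows")
    members: dict[str, list[str]] = {}
    for gene, cls in rows:
        members.setdefault(cls, []).append(gene)
    return TemplateSet(members)


def write_template(templates: TemplateSet, path) -> None:
    templates.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

class GeneSetCollection(Mapping):
    """Named, non-empty gene sets with optional descriptions."""

    def __init__(self, sets: Mapping[str, Sequence[str]],
                 descriptions: Mapping[str, str] | None = None):
        cleaned: dict[str, tuple[str, ...]] = {}
        for name, genes in sets.items():
            name = str(name)
            if name in cleaned:
                raise ValidationError(f"gene set {name!r} listed twice")
            genes = tuple(dict.fromkeys(str(g) for g in genes))
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = genes
        self._sets = cleaned
        self.descriptions = {str(k): str(v) for k, v in (descriptions or {}).items()}

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self._sets)} sets)"


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description and >=1 gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValidationError(f"{path}: gene set {name!r} listed twice")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


# ---------------------------------------------------------------------------
# labels and predictions
# ---------------------------------------------------------------------------

def read_labels(path) -> pd.Series:
    """Read a two-column (sample, label) table into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 tab-separated columns (sample, label)")
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")
    dup = series.index[series.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate sample ids: {sorted(dup)}")
    return series


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample": labels.index, "label": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def write_predictions(preds: pd.DataFrame, path) -> None:
    """Write a prediction table as TSV.

    Columns: sample, prediction, one similarity column per class, p_value,
    fdr.  Unassigned samples carry the literal ``NA`` in the prediction
    column.
    """
    cols = [c for c in preds.columns if c != "tie_flag"]
    out = preds[cols].copy()
    out.insert(0, "sample", preds.index)
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    """Read a table written by :func:`write_predictions`.

    The ``NA`` prediction literal is preserved as a string, not parsed as
    missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in df.columns or "prediction" not in df.columns:
        raise ParseError(f"{path}: missing 'sample'/'prediction' columns")
    df = df.set_index("sample")
    df.index.name = None
    for col in df.columns:
        if col != "prediction":
            df[col] = pd.to_numeric(df[col])
    return df
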