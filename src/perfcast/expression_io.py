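"""Real expression-matrix ingestion and preprocessing.

Reads delimited text matrices (samples x genes plus a class column), applies
the study inclusion filter (binary classes, at least 10 control samples),
log2-transforms values when they are not already on log scale, keeps the 10%
most variable genes, and balances classes by a smoothed bootstrap of the
minority class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "load_expression",
    "inclusion_filter",
    "preprocess",
    "balance",
]

# values above this are assumed to be raw intensities needing a log2 transform
LOG_SCALE_MAX = 30.0


@dataclass
class ExpressionTable:
    """A samples x genes numeric matrix with categorical class labels."""

    values: pd.DataFrame           # rows = samples, columns = genes
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels must match the sample count")
        if len(self.labels) == 0:
            raise ValueError("empty table")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            logger.warning("deduplicating %d duplicate gene ids", len(dupes))
            self.values.columns = _dedupe(list(self.values.columns))

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _dedupe(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for nm in names:
        if nm in seen:
            seen[nm] += 1
            out.append(f"{nm}.{seen[nm]}")
        else:
            seen[nm] = 0
            out.append(nm)
    return out


def load_expression(
    path, fmt: str | None = None, class_column: str = "class"
) -> ExpressionTable:
    """Read a delimited expression table with a class-label column.

    ``fmt`` is 'tsv' or 'csv'; inferred from the extension when omitted.
    Non-numeric expression cells raise an error naming the offending cell.
    """
    if fmt is None:
        fmt = "csv" if str(path).endswith(".csv") else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if class_column not in df.columns:
        raise ValueError(f"missing class column {class_column!r}")
    labels = df.pop(class_column).astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = converted
    return ExpressionTable(values=df, labels=labels)


def inclusion_filter(
    table: ExpressionTable,
    min_controls: int = 10,
    control_label: str | None = None,
) -> tuple[bool, str]:
    """Study inclusion rule: binary classes with enough control samples.

    The control class is the given label, or else a label containing
    'control'/'normal' (case-insensitive), or else the lexicographically
    first label.
    """
    counts = table.labels.value_counts()
    if len(counts) != 2:
        return False, f"non-binary ({len(counts)} classes)"
    control = _control_label(table.labels, control_label)
    n_controls = int(counts.get(control, 0))
    if n_controls < min_controls:
        return False, f"only {n_controls} control samples (need {min_controls})"
    return True, "ok"


def _control_label(labels: pd.Series, control_label: str | None) -> str:
    uniq = sorted(labels.unique())
    if control_label is not None:
        if control_label not in uniq:
            raise ValueError(f"control label {control_label!r} not present")
        return control_label
    for lab in uniq:
        if "control" in lab.lower() or "normal" in lab.lower():
            return lab
    return uniq[0]


def preprocess(
    table: ExpressionTable,
    top_fraction: float = 0.10,
    control_label: str | None = None,
    name: str = "expression",
) -> LabeledDataset:
    """Log2 transform (if needed) and keep the most variable genes.

    Values are log2-transformed unless the table already looks log-scaled
    (maximum below 30). Non-positive values are shifted by ``min + 1``
    before the log (logged). The ``ceil(top_fraction * G)`` genes with the
    highest post-log variance are retained. Control samples get label 0.
    """
    ok, reason = inclusion_filter(table, control_label=control_label)
    if not ok:
        raise ValueError(f"table fails inclusion filter: {reason}")
    V = table.values.to_numpy(dtype=float)
    if V.max() >= LOG_SCALE_MAX:
        if V.min() <= 0:
            offset = -V.min() + 1.0
            logger.warning("shifting values by %.3f before log2", offset)
            V = V + offset
        V = np.log2(V)
    n_keep = math.ceil(top_fraction * V.shape[1])
    variances = V.var(axis=0, ddof=1)
    keep = np.sort(np.argsort(-variances, kind="stable")[:n_keep])
    control = _control_label(table.labels, control_label)
    y = (table.labels != control).astype(int).to_numpy()
    return LabeledDataset(
        X=V[:, keep],
        y=y,
        feature_names=[str(table.values.columns[j]) for j in keep],
        name=name,
    )


def balance(ds: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Balance classes by a smoothed bootstrap of the minority class.

    Minority rows are resampled with replacement and jittered with Gaussian
    noise whose per-feature bandwidth follows a Silverman-type rule,
    ``h_j = sd_j * (4 / ((d + 2) * n_min))^(1 / (d + 4))`` — synthetic
    samples stay in the neighborhood of observed minority samples.
    """
    y = ds.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to balance")
    if counts[0] == counts[1]:
        return ds
    minority = int(np.argmin(counts))
    need = int(counts.max() - counts.min())
    rows = np.flatnonzero(y == minority)
    d = ds.n_features
    n_min = len(rows)
    sd = ds.X[rows].std(axis=0, ddof=1)
    h = sd * (4.0 / ((d + 2) * n_min)) ** (1.0 / (d + 4))
    rng = np.random.default_rng(seed)
    picks = rng.choice(rows, size=need, replace=True)
    synth = ds.X[picks] + rng.normal(0.0, 1.0, size=(need, d)) * h
    X_new = np.vstack([ds.X, synth])
    y_new = np.concatenate([y, np.full(need, minority)])
    return LabeledDataset(
        X=X_new,
        y=y_new,
        feature_names=list(ds.feature_names),
        name=f"{ds.name}_balanced",
    )
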