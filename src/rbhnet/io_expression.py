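"""Loading, validation and preprocessing of gene-by-sample expression matrices.

Matrices are delimited text with a header row of sample names and gene
symbols in the first column. Labels files map each sample to ``case`` or
``control`` (optionally plus a subtype). Preprocessing follows the
filter-then-transform order: drop genes with too many zeros on the raw
scale, then log2-transform with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
VALID_LABELS = frozenset({CASE, CONTROL})


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with case/control sample labels.

    Attributes
    ----------
    dataset_id : str
        Short identifier, unique within a collection.
    disease_group : str
        Group label the dataset belongs to (e.g. ``"AD"``, ``"LC"``).
    matrix : numpy.ndarray
        Real-valued array of shape ``(n_genes, n_samples)``.
    gene_ids : list of str
        Unique gene symbols, row-aligned with ``matrix``.
    sample_ids : list of str
        Unique sample names, column-aligned with ``matrix``.
    labels : list of str
        Per-sample label, each ``"case"`` or ``"control"``.
    subtype : list of str or None
        Optional per-sample subtype labels.
    log_scale : bool
        True when ``matrix`` is on log2 scale.
    """

    dataset_id: str
    disease_group: str
    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    subtype: list[str] | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        if self.subtype is not None:
            self.subtype = list(self.subtype)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = self.matrix.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{self.dataset_id}: {len(self.gene_ids)} gene ids for {n} rows"
            )
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{self.dataset_id}: {len(self.sample_ids)} sample ids for {m} columns"
            )
        if len(set(self.gene_ids)) != n:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"{self.dataset_id}: duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != m:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"{self.dataset_id}: duplicate sample ids: {dupes[:5]}")
        if len(self.labels) != m:
            raise ValueError(f"{self.dataset_id}: {len(self.labels)} labels for {m} samples")
        bad = sorted(set(self.labels) - VALID_LABELS)
        if bad:
            raise ValueError(f"{self.dataset_id}: invalid labels {bad}; expected case/control")
        if CASE not in self.labels or CONTROL not in self.labels:
            raise ValueError(f"{self.dataset_id}: need at least one case and one control sample")
        if self.subtype is not None and len(self.subtype) != m:
            raise ValueError(f"{self.dataset_id}: subtype length mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.dataset_id}: matrix contains missing/non-finite values")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([lab == CASE for lab in self.labels], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FoldChangeVector:
    """Per-gene log2 fold change: mean over cases minus mean over controls."""

    dataset_id: str
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("fold-change vector length does not match gene ids")


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it in seen and it not in out:
            out.append(it)
        seen.add(it)
    return out


def read_labels(labels_path: str) -> pd.DataFrame:
    """Read a 2/3-column delimited labels file (sample_id, label[, subtype])."""
    df = pd.read_csv(labels_path, sep=None, engine="python", header=None, dtype=str,
                     comment="#")
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in VALID_LABELS:  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected at least 2 columns (sample, label)")
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.iloc[:, :2]
    df.columns = ["sample_id", "label", "subtype"][: df.shape[1]]
    df["sample_id"] = df["sample_id"].str.strip()
    df["label"] = df["label"].str.strip().str.lower()
    bad = sorted(set(df["label"]) - VALID_LABELS)
    if bad:
        raise ValueError(f"{labels_path}: invalid labels {bad}; expected case/control")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{labels_path}: duplicate sample ids {dupes[:5]}")
    return df.set_index("sample_id")


def read_expression(
    path: str,
    labels_path: str,
    dataset_id: str,
    disease_group: str,
    log_scale: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix plus its sample labels.

    The matrix is delimited text (TSV or CSV, sniffed) with sample names in
    the header and gene symbols in the first column. Samples not present in
    the labels file raise; duplicate gene symbols are collapsed to the row
    with maximal variance.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
        raise ValueError(
            f"{path}: non-numeric value in column {col!r}"
            + (f", row {bad_rows[0]!r}" if bad_rows else "")
        )
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")

    lab = read_labels(labels_path)
    matrix_samples = list(df.columns)
    missing = [s for s in matrix_samples if s not in lab.index]
    if len(missing) == len(matrix_samples):
        raise ValueError(
            f"{dataset_id}: no overlap between matrix samples and labels in {labels_path}"
        )
    if missing:
        raise ValueError(f"{dataset_id}: samples missing from labels file: {missing}")

    df = collapse_duplicate_genes(df)

    labels = [lab.loc[s, "label"] for s in df.columns]
    subtype = None
    if "subtype" in lab.columns and lab["subtype"].notna().any():
        subtype = [
            (None if pd.isna(lab.loc[s, "subtype"]) else str(lab.loc[s, "subtype"]))
            for s in df.columns
        ]
    return ExpressionDataset(
        dataset_id=dataset_id,
        disease_group=disease_group,
        matrix=df.to_numpy(dtype=float),
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        labels=labels,
        subtype=subtype,
        log_scale=log_scale,
    )


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene-symbol rows, keeping the max-variance row.

    Order of first occurrence is preserved.
    """
    if not df.index.duplicated().any():
        return df
    variances = df.var(axis=1, ddof=1).to_numpy()
    best: dict[str, int] = {}
    for i, g in enumerate(df.index):
        j = best.get(g)
        if j is None or variances[i] > variances[j]:
            best[g] = i
    order: list[int] = []
    seen: set[str] = set()
    for g in df.index:
        if g not in seen:
            order.append(best[g])
            seen.add(g)
    return df.iloc[order]


def filter_zero_genes(
    ds: ExpressionDataset, max_zero_fraction: float = 0.30
) -> ExpressionDataset:
    """Drop genes whose zero fraction strictly exceeds ``max_zero_fraction``.

    Intended for raw-scale (non-log) matrices; gene order is preserved.
    """
    zero_frac = (ds.matrix == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError(f"{ds.dataset_id}: zero-fraction filter removed every gene")
    return replace(
        ds,
        matrix=ds.matrix[keep],
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
    )


def log2_transform(ds: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Replace each entry x by log2(x + pseudocount); sets ``log_scale``."""
    if ds.log_scale:
        raise ValueError(f"{ds.dataset_id}: matrix is already log-scale")
    if (ds.matrix < 0).any():
        i, j = np.argwhere(ds.matrix < 0)[0]
        raise ValueError(
            f"{ds.dataset_id}: negative entry at gene {ds.gene_ids[i]!r}, "
            f"sample {ds.sample_ids[j]!r}; cannot log-transform"
        )
    return replace(ds, matrix=np.log2(ds.matrix + pseudocount), log_scale=True)


def fold_change(ds: ExpressionDataset) -> FoldChangeVector:
    """Per-gene case-mean minus control-mean on the log2-scale matrix."""
    if not ds.log_scale:
        raise ValueError(f"{ds.dataset_id}: fold change requires a log2-scale matrix")
    cm = ds.case_mask
    if not cm.any() or cm.all():
        raise ValueError(f"{ds.dataset_id}: need both case and control samples")
    fc = ds.matrix[:, cm].mean(axis=1) - ds.matrix[:, ~cm].mean(axis=1)
    return FoldChangeVector(dataset_id=ds.dataset_id, gene_ids=list(ds.gene_ids), values=fc)
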