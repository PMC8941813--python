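"""Expression preprocessing: quantile normalization, median-polish
summarization of probe-level data, and duplicate-gene collapsing.

Normalization here is plain quantile normalization (each sample column is
forced onto the across-sample mean distribution); no model-based
background correction is applied. Raw-scale input can be log2-transformed
with a +1 offset via :func:`log2_transform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from surfscore.errors import FormatError, ValidationError

GROUPS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity matrix with tumor/normal labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.groups = list(self.groups)
        if self.values.ndim != 2:
            raise ValidationError("values: expected a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids: length does not match row count")
        if len(self.sample_ids) != n_samples:
            raise ValidationError("sample_ids: length does not match column count")
        if len(self.groups) != n_samples:
            raise ValidationError("groups: every sample needs a group label")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("sample_ids: duplicate sample identifiers")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValidationError(f"groups: unknown labels {sorted(bad)}; expected {GROUPS}")
        if not np.all(np.isfinite(self.values)):
            rows, cols = np.nonzero(~np.isfinite(self.values))
            cells = [(self.gene_ids[r], self.sample_ids[c]) for r, c in zip(rows[:5], cols[:5])]
            raise ValidationError(f"values: non-finite entries at {cells} (first 5 shown)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ProbeMatrix:
    """Probes x samples matrix with a probe -> gene map."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    probe_to_gene: dict[str, str]
    groups: list[str] | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values: expected a 2-D probes x samples matrix")
        if len(self.probe_ids) != self.values.shape[0]:
            raise ValidationError("probe_ids: length does not match row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValidationError("sample_ids: length does not match column count")
        missing = [p for p in self.probe_ids if p not in self.probe_to_gene]
        if missing:
            raise ValidationError(f"probe_to_gene: probes without a gene: {missing[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values: non-finite entries in probe matrix")


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    # Reference distribution = row-wise mean of the sorted columns; tied
    # values within a column share the mean reference value over their
    # tied rank span (keeps the transform idempotent).
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValidationError("values: need a 2-D matrix with >=1 column")
    if not np.all(np.isfinite(values)):
        rows, cols = np.nonzero(~np.isfinite(values))
        raise ValidationError(
            f"values: non-finite cells at rows {rows[:5].tolist()}, cols {cols[:5].tolist()}"
        )
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        normalized = np.empty(n_rows)
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            normalized[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = normalized
    return out


def quantile_normalize(matrix: ExpressionMatrix | ProbeMatrix) -> ExpressionMatrix | ProbeMatrix:
    """Quantile-normalize sample columns onto their common mean distribution.

    Every column's sorted value vector afterwards equals the across-column
    mean of sorted columns; within-column rank order is preserved (ties
    stay tied). Accepts and returns either matrix type.
    """
    return replace(matrix, values=_quantile_normalize_values(matrix.values))


def log2_transform(matrix: ExpressionMatrix | ProbeMatrix, offset: float = 1.0):
    """log2(x + offset) for raw-scale input."""
    if np.any(matrix.values + offset <= 0):
        raise ValidationError("values: log2 transform undefined for values <= -offset")
    return replace(matrix, values=np.log2(matrix.values + offset))


def _median_polish_block(
    block: np.ndarray, max_sweeps: int = 10, tol_per_cell: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of one probes x samples block.

    Returns (overall, row_effects, col_effects, residuals). Stops when the
    sweep-to-sweep change in the total absolute residual is below
    ``tol_per_cell * block.size`` or after ``max_sweeps`` sweeps.
    """
    residual = np.asarray(block, dtype=float).copy()
    if residual.size == 0:
        raise ValidationError("block: empty probe block")
    n_rows, n_cols = residual.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    tol = tol_per_cell * residual.size
    last_abs = np.abs(residual).sum()
    for _ in range(max_sweeps):
        row_delta = np.median(residual, axis=1)
        residual -= row_delta[:, None]
        row_eff += row_delta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        col_delta = np.median(residual, axis=0)
        residual -= col_delta[None, :]
        col_eff += col_delta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        abs_now = np.abs(residual).sum()
        if abs(last_abs - abs_now) < tol:
            break
        last_abs = abs_now
    return overall, row_eff, col_eff, residual


def median_polish_summarize(probes: ProbeMatrix) -> ExpressionMatrix:
    """Summarize probe-level data to one row per gene via median polish.

    Each gene's probe block is polished independently; the per-sample
    gene summary is ``overall + column effect``. Gene rows are emitted in
    order of first probe appearance.
    """
    gene_order: list[str] = []
    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(probes.probe_ids):
        gene = probes.probe_to_gene[probe]
        if gene not in gene_rows:
            gene_rows[gene] = []
            gene_order.append(gene)
        gene_rows[gene].append(i)
    summaries = np.empty((len(gene_order), len(probes.sample_ids)))
    for g, gene in enumerate(gene_order):
        block = probes.values[gene_rows[gene], :]
        overall, _, col_eff, _ = _median_polish_block(block)
        summaries[g, :] = overall + col_eff
    groups = probes.groups if probes.groups is not None else ["tumor"] * len(probes.sample_ids)
    return ExpressionMatrix(
        values=summaries,
        gene_ids=gene_order,
        sample_ids=list(probes.sample_ids),
        groups=groups,
        dataset_id=probes.dataset_id,
    )


def collapse_duplicate_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene id, the row with the highest mean value.

    Ties break to the lowest original row index. No-op when gene ids are
    already unique.
    """
    if len(set(matrix.gene_ids)) == len(matrix.gene_ids):
        return matrix
    means = matrix.values.mean(axis=1)
    best: dict[str, int] = {}
    order: list[str] = []
    for i, gene in enumerate(matrix.gene_ids):
        if gene not in best:
            best[gene] = i
            order.append(gene)
        elif means[i] > means[best[gene]]:
            best[gene] = i
    keep = [best[g] for g in order]
    return replace(matrix, values=matrix.values[keep, :], gene_ids=order)


# ---------------------------------------------------------------------------
# TSV readers/writers (dialects produced by surfscore.synthetic)
# ---------------------------------------------------------------------------

def read_expression_tsv(
    expr_path: str | Path, meta_path: str | Path, dataset_id: str = ""
) -> ExpressionMatrix:
    """Load an expression TSV (``gene_id`` + sample columns) and its
    sample-metadata TSV (``sample_id<TAB>group``)."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    if expr.index.name != "gene_id":
        raise FormatError(f"{expr_path}: first column must be 'gene_id', found {expr.index.name!r}")
    meta = pd.read_csv(meta_path, sep="\t")
    if list(meta.columns) != ["sample_id", "group"]:
        raise FormatError(
            f"{meta_path}: expected columns ['sample_id', 'group'], found {list(meta.columns)}"
        )
    group_of = dict(zip(meta["sample_id"].astype(str), meta["group"].astype(str)))
    missing = [s for s in expr.columns if s not in group_of]
    if missing:
        raise FormatError(f"{meta_path}: samples without a group label: {missing[:5]}")
    matrix = ExpressionMatrix(
        values=expr.to_numpy(dtype=float),
        gene_ids=[str(g) for g in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        groups=[group_of[str(s)] for s in expr.columns],
        dataset_id=dataset_id or Path(expr_path).stem,
    )
    return collapse_duplicate_genes(matrix)


def write_expression_tsv(matrix: ExpressionMatrix, expr_path: str | Path, meta_path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(expr_path, sep="\t", float_format="%.6f")
    meta = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.groups})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_geo_series_matrix(path: str | Path, dataset_id: str = "") -> pd.DataFrame:
    """Convenience reader for GEO series-matrix text: returns the
    tab-delimited block between the table-begin/table-end markers as a
    DataFrame (rows indexed by the ID column). Never required by tests."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_begin"))
        end = next(i for i, ln in enumerate(lines) if ln.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise FormatError(f"{path}: series-matrix table markers not found") from exc
    rows = [ln.split("\t") for ln in lines[start + 1 : end] if ln.strip()]
    if not rows:
        raise FormatError(f"{path}: empty series-matrix table")
    header = [c.strip('"') for c in rows[0]]
    data = [[c.strip('"') for c in r] for r in rows[1:]]
    frame = pd.DataFrame(data, columns=header).set_index(header[0])
    return frame.apply(pd.to_numeric, errors="coerce")
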