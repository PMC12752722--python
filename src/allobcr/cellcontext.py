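"""Cell-type-resolved repertoire statistics for single-cell samples.

Barcoded clonotypes are partitioned by an externally supplied cell-type
annotation (clustering/annotation itself is consumed, never computed here).
The headline statistic is the fold ratio of pooled BCR read abundance between
plasma cells and B cells; isotype abundances can additionally be correlated
with per-sample immune-infiltration scores (CIBERSORT-ABS-style, consumed as
given).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import RepertoireSample
from .stats import RepertoireSummary, is_normal

__all__ = [
    "CellAnnotation", "join_barcodes", "celltype_fold",
    "correlate_infiltration",
]

B_CELL_TYPES = ("naive B", "memory B")
UNASSIGNED = "unassigned"


@dataclass
class CellAnnotation:
    """Barcode -> (cell type, sample, group) mapping with unique barcodes."""

    table: pd.DataFrame  # columns: cell_id, cell_type, sample_id, group

    def __post_init__(self) -> None:
        required = {"cell_id", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing column(s) {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("annotation has duplicate cell barcodes")

    @classmethod
    def read_tsv(cls, path) -> "CellAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())


def join_barcodes(
    sample: RepertoireSample, annotation: CellAnnotation,
) -> dict[str, RepertoireSample]:
    """Partition a single-cell sample's clonotypes by annotated cell type.

    Barcodes absent from the annotation land in the ``"unassigned"`` bucket.
    Raises if no barcode overlaps the annotation at all.
    """
    if sample.modality != "single_cell":
        raise ValueError("join_barcodes requires a single-cell sample")
    df = sample.clonotypes
    mapping = annotation.table.set_index("cell_id")["cell_type"]
    types = df["cell_barcode"].map(mapping)
    if types.notna().sum() == 0:
        raise ValueError(
            "no clonotype barcode overlaps the annotation (join error)"
        )
    types = types.fillna(UNASSIGNED)
    partitions: dict[str, RepertoireSample] = {}
    for cell_type, sub in df.groupby(types, sort=True):
        partitions[str(cell_type)] = RepertoireSample(
            sample_id=sample.sample_id, group=sample.group,
            clonotypes=sub.reset_index(drop=True), modality="single_cell",
        )
    return partitions


def celltype_fold(
    partitions: dict[str, RepertoireSample],
    type_a: str = "plasma",
    type_b: str = "B",
    combine_b: bool = True,
    per_cell: bool = False,
) -> float:
    """Fold ratio of pooled BCR read abundance, ``type_a`` over ``type_b``.

    ``type_b="B"`` with ``combine_b=True`` pools naive and memory B cells in
    the denominator. ``per_cell=True`` divides each side by its number of
    distinct barcodes first. An absent cell type or zero denominator reads
    yields NaN (flagged as undefined rather than raising).
    """
    def side(label: str) -> tuple[int, int]:
        if label == "B" and combine_b:
            members = [t for t in B_CELL_TYPES if t in partitions]
        else:
            members = [label] if label in partitions else []
        reads = sum(partitions[t].total_reads for t in members)
        cells = sum(
            partitions[t].clonotypes["cell_barcode"].nunique() for t in members
        )
        return reads, cells

    reads_a, cells_a = side(type_a)
    reads_b, cells_b = side(type_b)
    if cells_a == 0 or cells_b == 0:
        return math.nan
    if per_cell:
        if cells_a == 0 or cells_b == 0:
            return math.nan
        num, den = reads_a / cells_a, reads_b / cells_b
    else:
        num, den = float(reads_a), float(reads_b)
    return num / den if den > 0 else math.nan


def correlate_infiltration(
    summaries: list[RepertoireSummary],
    scores: pd.DataFrame,
    cell_types: list[str] | None = None,
    levels: list[str] = ("IGHA", "IGHD", "IGHE", "IGHG", "IGHM"),
    group: str | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Correlate isotype read abundance with infiltration scores.

    ``scores`` is samples x cell types (non-negative, absolute-mode
    deconvolution contract). Per (cell type, isotype level) pair the
    normality-gated correlation and p-value are returned, restricted to
    ``group`` when given. Constant score vectors give NaN entries, flagged.
    """
    if (scores.to_numpy(dtype=float) < 0).any():
        raise ValueError("infiltration scores must be non-negative")
    cell_types = list(cell_types or scores.columns)
    use = [s for s in summaries if group is None or s.group == group]
    ids = [s.sample_id for s in use if s.sample_id in scores.index]
    if len(ids) < 3:
        raise ValueError(f"need >=3 shared samples, got {len(ids)}")
    by_id = {s.sample_id: s for s in use}
    rows = []
    for level in levels:
        metric = np.array([by_id[i].metric(level, "reads") for i in ids])
        for ct in cell_types:
            x = scores.loc[ids, ct].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(metric) == 0:
                rows.append((ct, level, math.nan, math.nan, "undefined", False))
                continue
            if method == "auto":
                use_m = (
                    "pearson" if (is_normal(x) and is_normal(metric))
                    else "spearman"
                )
            else:
                use_m = method
            fn = sps.pearsonr if use_m == "pearson" else sps.spearmanr
            r, p = fn(x, metric)
            rows.append((ct, level, float(r), float(p), use_m, True))
    return pd.DataFrame(
        rows, columns=["cell_type", "level", "r", "p", "method", "defined"]
    )
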