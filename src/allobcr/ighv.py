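"""IGHV gene usage: matrices, the low-expression exclusion rule, top genes.

Usage is the read abundance attributed to each allele-trimmed IGHV gene in
each sample. The exclusion rule drops every gene whose abundance is low
(default: exactly zero) in at least a given fraction of the designated
group's samples — implemented exactly as printed, with a ``keep-if-expressed``
alternative reading available (see ``rule``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import RepertoireSample

__all__ = [
    "UsageMatrix", "build_usage", "exclude_low_expression",
    "top_genes", "intersect_top",
]


@dataclass
class UsageMatrix:
    """IGHV usage: genes x samples read abundances plus group labels."""

    values: pd.DataFrame                  # genes (rows) x samples (columns)
    groups: pd.Series = field(default=None)  # sample_id -> group label

    @property
    def log2_values(self) -> pd.DataFrame:
        """log2(x + 1) view used for heatmap-style reporting."""
        return np.log2(self.values + 1.0)

    def group_samples(self, group: str) -> list[str]:
        ids = list(self.groups[self.groups == group].index)
        if not ids:
            raise ValueError(f"group {group!r} not present in usage matrix")
        return ids


def build_usage(samples: list[RepertoireSample]) -> UsageMatrix:
    """Aggregate heavy-chain read counts per allele-trimmed IGHV gene.

    Alleles of the same gene are merged by summation; genes absent from a
    sample get 0. Samples with no IGHV-resolved records yield all-zero
    columns.
    """
    cols = {}
    groups = {}
    for s in samples:
        df = s.clonotypes
        mask = (df["chain_level"] == "heavy") & df["v_call"].str.startswith("IGHV")
        genes = df.loc[mask, "v_call"].str.split("*").str[0]
        cols[s.sample_id] = (
            df.loc[mask, "read_count"].groupby(genes).sum()
        )
        groups[s.sample_id] = s.group
    values = pd.DataFrame(cols).fillna(0.0).sort_index()
    values.index.name = "gene"
    return UsageMatrix(values=values, groups=pd.Series(groups, name="group"))


def exclude_low_expression(
    matrix: UsageMatrix,
    group: str,
    frac: float = 0.10,
    low_threshold: float = 0.0,
    rule: str = "as-printed",
) -> tuple[UsageMatrix, list[str]]:
    """Apply the low-expression exclusion rule within one group.

    ``rule="as-printed"`` (default) drops a gene when its abundance is low
    (<= ``low_threshold``) in at least ``frac`` of the group's samples.
    ``rule="keep-if-expressed"`` is the complementary common reading: keep a
    gene only when it is expressed above the threshold in at least ``frac``
    of the group's samples. Returns the retained matrix and the dropped genes.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"frac must be in [0, 1], got {frac}")
    if rule not in ("as-printed", "keep-if-expressed"):
        raise ValueError(f"unknown rule {rule!r}")
    ids = matrix.group_samples(group)
    sub = matrix.values[ids]
    n_low = (sub <= low_threshold).sum(axis=1)
    if rule == "as-printed":
        drop = n_low / len(ids) >= frac
    else:
        drop = (len(ids) - n_low) / len(ids) < frac
    dropped = list(matrix.values.index[drop])
    kept = UsageMatrix(values=matrix.values[~drop.values], groups=matrix.groups)
    return kept, dropped


def top_genes(matrix: UsageMatrix, group: str, k: int) -> list[str]:
    """Genes ranked by group-mean abundance, top ``k``.

    Ties are broken lexicographically on the gene name so the ranking is
    deterministic. Asking for more genes than exist returns all with a
    warning.
    """
    if matrix.values.empty:
        raise ValueError("usage matrix has no genes")
    ids = matrix.group_samples(group)
    means = matrix.values[ids].mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    if k > len(order):
        warnings.warn(
            f"requested top {k} genes but only {len(order)} available",
            stacklevel=2,
        )
        return order
    return order[:k]


def intersect_top(lists: list[list[str]]) -> list[str]:
    """Genes common to all ranked lists, in the first list's rank order."""
    if not lists:
        return []
    shared = set(lists[0])
    for other in lists[1:]:
        shared &= set(other)
    return [g for g in lists[0] if g in shared]
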