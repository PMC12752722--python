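"""Three-criterion candidate-gene discovery against the IGHG repertoire.

A gene is a candidate when it simultaneously shows

1. a strong correlation (|r| > 0.7 by default) with the per-sample number of
   IGHG clonotypes (abundance),
2. a strong correlation (|r| > 0.7) with the per-sample IGHG CPK, and
3. differential expression between the clinical groups at Hochberg-adjusted
   p < 0.05.

The default uses |r| for both correlation criteria because a negative CPK
correlation (more expansion, lower diversity) is the biologically expected
signature of an expansion-linked gene; ``signed=True`` restores the literal
one-sided rule. Correlation and DE tests are normality-gated in the same way
as the repertoire statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import gated_two_sample_test, is_normal

__all__ = [
    "correlate_with_metric", "hochberg_adjust", "differential_expression",
    "select_candidates", "CandidateSelection",
]


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.columns.duplicated().any():
        raise ValueError("expression matrix has duplicate sample ids")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def correlate_with_metric(
    expr: pd.DataFrame,
    metric: pd.Series,
    method: str = "auto",
) -> pd.DataFrame:
    """Correlate each gene (row of ``expr``) with a per-sample metric.

    ``method="auto"`` applies the normality gate per gene: Pearson when both
    the gene vector and the metric pass Shapiro-Wilk, else Spearman. Only
    samples present in both inputs are used (>= 3 required). Genes or metrics
    with zero variance yield NaN coefficients, flagged in ``defined``.

    Returns a frame indexed by gene: r, p, method, n, defined.
    """
    if method not in ("auto", "pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    _check_expression(expr)
    shared = [s for s in expr.columns if s in metric.index]
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 overlapping samples, got {len(shared)}"
        )
    m = metric[shared].to_numpy(dtype=float)
    metric_normal = is_normal(m)
    m_const = np.ptp(m) == 0
    rows = []
    for gene, x in expr[shared].iterrows():
        x = x.to_numpy(dtype=float)
        if m_const or np.ptp(x) == 0:
            rows.append((gene, math.nan, math.nan, "undefined", len(shared), False))
            continue
        if method == "auto":
            use = "pearson" if (metric_normal and is_normal(x)) else "spearman"
        else:
            use = method
        if use == "pearson":
            r, p = sps.pearsonr(x, m)
        else:
            r, p = sps.spearmanr(x, m)
        rows.append((gene, float(r), float(p), use, len(shared), True))
    return pd.DataFrame(
        rows, columns=["gene", "r", "p", "method", "n", "defined"]
    ).set_index("gene")


def hochberg_adjust(pvalues) -> np.ndarray:
    """Hochberg step-up adjusted p-values (FWER control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    return multipletests(p, method="simes-hochberg")[1]


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene two-sample DE test with Hochberg adjustment.

    ``test`` is ``"wilcoxon"`` (default — expression rarely passes the
    normality gate), ``"t"``, or ``"auto"`` for the gate. Genes constant
    across all used samples get p = 1, flagged in ``degenerate``. Returns a
    frame indexed by gene: p, p_adj, test, degenerate.
    """
    if test not in ("wilcoxon", "t", "auto"):
        raise ValueError(f"unknown DE test {test!r}")
    _check_expression(expr)
    ids_a = [s for s in expr.columns if groups.get(s) == group_a]
    ids_b = [s for s in expr.columns if groups.get(s) == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs >=2 samples for DE testing")
    rows = []
    for gene in expr.index:
        a = expr.loc[gene, ids_a].to_numpy(dtype=float)
        b = expr.loc[gene, ids_b].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((gene, 1.0, "degenerate", True))
            continue
        if test == "auto":
            p, used = gated_two_sample_test(a, b)
        elif test == "t":
            p, used = float(sps.ttest_ind(a, b).pvalue), "t"
        else:
            from .stats import rank_test
            p, used = rank_test(a, b), "wilcoxon"
        rows.append((gene, p, used, False))
    out = pd.DataFrame(
        rows, columns=["gene", "p", "test", "degenerate"]
    ).set_index("gene")
    out["p_adj"] = hochberg_adjust(out["p"].to_numpy())
    return out[["p", "p_adj", "test", "degenerate"]]


@dataclass
class CandidateSelection:
    """Selected genes plus the seven Venn-region counts of the three criteria."""

    genes: list[str]
    venn: dict[str, int]     # keys like "abundance", "abundance&cpk", ...
    table: pd.DataFrame      # per-gene r/p values and pass flags


def select_candidates(
    r_abundance: pd.Series,
    r_cpk: pd.Series,
    p_adj: pd.Series,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    signed: bool = False,
) -> CandidateSelection:
    """Intersect the three criteria into the candidate-gene list.

    ``signed=False`` (default) uses |r| > ``r_threshold`` for both
    correlation criteria; ``signed=True`` requires r > ``r_threshold``.
    NaN correlations never pass. The result is independent of gene order
    (genes are reported sorted).
    """
    genes = sorted(set(r_abundance.index) & set(r_cpk.index) & set(p_adj.index))
    ra = r_abundance[genes].to_numpy(dtype=float)
    rc = r_cpk[genes].to_numpy(dtype=float)
    pa = p_adj[genes].to_numpy(dtype=float)
    strength = (lambda r: r) if signed else np.abs
    with np.errstate(invalid="ignore"):
        pass_ab = strength(ra) > r_threshold
        pass_cpk = strength(rc) > r_threshold
    pass_ab &= np.isfinite(ra)
    pass_cpk &= np.isfinite(rc)
    pass_de = pa < alpha
    table = pd.DataFrame({
        "r_abundance": ra, "r_cpk": rc, "p_adj": pa,
        "pass_abundance": pass_ab, "pass_cpk": pass_cpk, "pass_de": pass_de,
        "selected": pass_ab & pass_cpk & pass_de,
    }, index=pd.Index(genes, name="gene"))
    regions = {
        "abundance": pass_ab & ~pass_cpk & ~pass_de,
        "cpk": ~pass_ab & pass_cpk & ~pass_de,
        "de": ~pass_ab & ~pass_cpk & pass_de,
        "abundance&cpk": pass_ab & pass_cpk & ~pass_de,
        "abundance&de": pass_ab & ~pass_cpk & pass_de,
        "cpk&de": ~pass_ab & pass_cpk & pass_de,
        "abundance&cpk&de": pass_ab & pass_cpk & pass_de,
    }
    venn = {name: int(mask.sum()) for name, mask in regions.items()}
    selected = [g for g, s in zip(genes, table["selected"]) if s]
    return CandidateSelection(genes=selected, venn=venn, table=table)
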