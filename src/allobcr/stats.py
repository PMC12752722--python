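"""Repertoire statistics: clonality bins, abundance, CPK and group tests.

Two per-sample statistics are computed at every level of the chain hierarchy:

* absolute abundance — the number of distinct clonotypes (and, alongside it,
  the number of CDR3 reads), and
* CPK — clonotypes per thousand CDR3 reads, ``1000 * n_clonotypes / n_reads``,
  the diversity statistic. Lower CPK at fixed reads means clonal expansion.
  CPK is undefined (NaN), never 0, on levels with no reads.

Group comparisons are normality-gated: Shapiro-Wilk at alpha = 0.05 on each
group; Student's t only when both groups pass, otherwise the Wilcoxon rank-sum
test with midranks and no continuity correction (exact enumeration when the
pooled values are tie-free and small).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import LEVEL_PARENT, LEVELS, RepertoireSample

__all__ = [
    "RepertoireSummary", "ClonalityBinning", "GroupComparison",
    "summarize", "bin_clonality", "compare_groups", "isotype_proportions",
    "is_normal", "rank_test", "gated_two_sample_test",
    "DEFAULT_BIN_EDGES",
]

NORMALITY_ALPHA = 0.05
#: exact rank-test enumeration is used up to this pooled size (tie-free data)
EXACT_RANK_LIMIT = 20


# ---------------------------------------------------------------------------
# normality-gated two-sample testing
# ---------------------------------------------------------------------------

def is_normal(values, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro-Wilk normality check; degenerate/short vectors fail the gate."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > alpha


def rank_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value (midranks, no continuity).

    Uses the exact permutation null when the pooled sample is tie-free and
    has at most :data:`EXACT_RANK_LIMIT` observations, else the tie-corrected
    normal approximation. Identical constant groups return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and len(pooled) <= EXACT_RANK_LIMIT else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=False, method=method,
    )
    return float(min(res.pvalue, 1.0))


def gated_two_sample_test(a, b) -> tuple[float, str]:
    """Normality-gated two-sample test: returns (two-sided p, test name)."""
    if is_normal(a) and is_normal(b):
        p = sps.ttest_ind(a, b).pvalue
        return float(p), "t"
    return rank_test(a, b), "wilcoxon"


# ---------------------------------------------------------------------------
# per-sample summaries
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSummary:
    """Abundance/read/CPK statistics of one sample at each hierarchy level.

    ``table`` is indexed by level (see :data:`allobcr.records.LEVELS`) with
    columns ``n_clonotypes``, ``n_reads``, ``cpk``.
    """

    sample_id: str
    group: str
    table: pd.DataFrame

    def metric(self, level: str, metric: str) -> float:
        """Look up one statistic; ``metric`` in {abundance, reads, cpk}."""
        col = {"abundance": "n_clonotypes", "reads": "n_reads", "cpk": "cpk"}[metric]
        return float(self.table.loc[level, col])


def _level_mask(df: pd.DataFrame, level: str) -> np.ndarray:
    if level == "total":
        return np.ones(len(df), dtype=bool)
    if level in ("heavy", "light"):
        return (df["chain_level"] == level).to_numpy()
    if level in ("IGHA", "IGHD", "IGHE", "IGHG", "IGHM"):
        return (df["isotype"] == level).to_numpy()
    return (df["subclass"] == level).to_numpy()


def summarize(sample: RepertoireSample) -> RepertoireSummary:
    """Compute abundance, reads and CPK at every level of the hierarchy.

    A level's CPK uses only that level's records: 1000 x clonotypes / reads,
    NaN when the level has no reads. An empty sample yields all-zero counts.
    """
    df = sample.clonotypes
    rows = []
    for level in LEVELS:
        mask = _level_mask(df, level)
        n_clono = int(mask.sum())
        n_reads = int(df.loc[mask, "read_count"].sum()) if n_clono else 0
        cpk = 1000.0 * n_clono / n_reads if n_reads > 0 else math.nan
        rows.append((level, n_clono, n_reads, cpk))
    table = pd.DataFrame(
        rows, columns=["level", "n_clonotypes", "n_reads", "cpk"]
    ).set_index("level")
    return RepertoireSummary(sample.sample_id, sample.group, table)


# ---------------------------------------------------------------------------
# clonality bins
# ---------------------------------------------------------------------------

#: copy-count partition of the positive integers: 0-1, 2-10, 11-50, 51-100, >=101
DEFAULT_BIN_EDGES = ((0, 1), (2, 10), (11, 50), (51, 100), (101, None))


@dataclass
class ClonalityBinning:
    """A partition of clonotype copy counts into labelled intervals."""

    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        lo_prev = None
        for lo, hi in self.edges:
            if hi is not None and hi < lo:
                raise ValueError(f"bin ({lo}, {hi}) is empty")
            if lo_prev is not None and lo != lo_prev + 1:
                raise ValueError("bin edges must partition the integers")
            lo_prev = hi
        if self.edges[-1][1] is not None:
            raise ValueError("last bin must be open-ended")

    @property
    def labels(self) -> list[str]:
        return [
            f"{lo}-{hi}" if hi is not None else f">={lo}"
            for lo, hi in self.edges
        ]

    def assign(self, counts) -> np.ndarray:
        """Bin index for each copy count (every count lands in exactly one)."""
        counts = np.asarray(counts)
        cut = np.array([lo for lo, _ in self.edges[1:]])
        return np.searchsorted(cut, counts, side="right")


def bin_clonality(
    samples: list[RepertoireSample],
    binning: ClonalityBinning | None = None,
) -> pd.DataFrame:
    """Per-sample clonality-bin occupancy: raw counts and proportions.

    Returns a tidy frame (sample_id, group, bin, n_clonotypes, proportion).
    Proportions sum to 1 for non-empty samples; empty samples are flagged
    with NaN proportions.
    """
    binning = binning or ClonalityBinning()
    rows = []
    for sample in samples:
        counts = sample.clonotypes["read_count"].to_numpy()
        idx = binning.assign(counts) if len(counts) else np.empty(0, int)
        occ = np.bincount(idx, minlength=len(binning.edges))
        total = occ.sum()
        for label, n in zip(binning.labels, occ):
            rows.append({
                "sample_id": sample.sample_id, "group": sample.group,
                "bin": label, "n_clonotypes": int(n),
                "proportion": n / total if total else math.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-group comparison of one repertoire metric at one level."""

    metric: str
    level: str
    group_a: str
    group_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    n_a: int
    n_b: int
    n_excluded: int
    test: str
    p_value: float
    fold: float       # mean(group_a) / mean(group_b)
    direction: str    # "a>b", "a<b" or "a=b"


def compare_groups(
    summaries: list[RepertoireSummary],
    group_a: str,
    group_b: str,
    metric: str = "abundance",
    level: str = "total",
) -> GroupComparison:
    """Normality-gated comparison of a per-sample metric between two groups.

    Undefined metric values (NaN CPK on empty levels) are excluded and
    reported in ``n_excluded``. The fold ratio is mean(a)/mean(b) of the
    usable per-sample values — the expansion-fold statistic.
    """
    vals: dict[str, list[float]] = {group_a: [], group_b: []}
    excluded = 0
    for s in summaries:
        if s.group not in vals:
            continue
        v = s.metric(level, metric)
        if math.isnan(v):
            excluded += 1
        else:
            vals[s.group].append(v)
    a = np.asarray(vals[group_a], dtype=float)
    b = np.asarray(vals[group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"compare_groups needs >=2 usable values per group "
            f"(got {len(a)} {group_a}, {len(b)} {group_b})"
        )
    p, test = gated_two_sample_test(a, b)
    mean_a, mean_b = a.mean(), b.mean()
    fold = mean_a / mean_b if mean_b != 0 else math.inf
    direction = "a>b" if mean_a > mean_b else ("a<b" if mean_a < mean_b else "a=b")
    return GroupComparison(
        metric=metric, level=level, group_a=group_a, group_b=group_b,
        values_a=a, values_b=b, n_a=len(a), n_b=len(b), n_excluded=excluded,
        test=test, p_value=p, fold=float(fold), direction=direction,
    )


# ---------------------------------------------------------------------------
# isotype composition
# ---------------------------------------------------------------------------

def isotype_proportions(summaries: list[RepertoireSummary]) -> pd.DataFrame:
    """Within-parent read-share of each hierarchy level, per sample and group.

    For every non-root level L (heavy/light within total, isotypes within
    heavy, subclasses within their isotype) the read proportion
    reads(L)/reads(parent) is reported per sample, plus two group aggregates:
    ``pooled`` (summing reads across the group's samples before dividing) and
    ``mean_of_samples``. Zero parent reads give NaN for that sample.
    """
    per_sample = []
    for s in summaries:
        for level, parent in LEVEL_PARENT.items():
            child = s.metric(level, "reads")
            par = s.metric(parent, "reads")
            per_sample.append({
                "sample_id": s.sample_id, "group": s.group, "level": level,
                "parent": parent, "n_reads": child, "parent_reads": par,
                "proportion": child / par if par > 0 else math.nan,
            })
    df = pd.DataFrame(per_sample)
    agg = (
        df.groupby(["group", "level", "parent"], as_index=False)
        .agg(n_reads=("n_reads", "sum"), parent_reads=("parent_reads", "sum"),
             mean_of_samples=("proportion", "mean"))
    )
    agg["pooled"] = np.where(
        agg["parent_reads"] > 0, agg["n_reads"] / agg["parent_reads"], math.nan
    )
    return df.merge(
        agg[["group", "level", "pooled", "mean_of_samples"]],
        on=["group", "level"], how="left",
    )


def summaries_to_frame(summaries: list[RepertoireSummary]) -> pd.DataFrame:
    """Tidy export: one row per sample x level with all three statistics."""
    frames = []
    for s in summaries:
        t = s.table.reset_index()
        t.insert(0, "sample_id", s.sample_id)
        t.insert(1, "group", s.group)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
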