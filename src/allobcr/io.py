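"""Readers and writers for clonotype tables.

Two dialects are supported:

* AIRR Rearrangement TSV — the community-standard schema (columns ``junction``,
  ``junction_aa``, ``v_call``, ``d_call``, ``j_call``, ``c_call``,
  ``duplicate_count``/``consensus_count``, ``cell_id``).
* TRUST4 report TSV — ``count  frequency  CDR3nt  CDR3aa  V  D  J  C`` with an
  optional ``cid`` barcode column; ``*``/``.`` placeholders denote missing gene
  calls and TCR loci are discarded.

Malformed rows are never dropped silently: every reader returns a
:class:`ReadReport` tallying merged, rejected and discarded rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .records import CLONOTYPE_COLUMNS, RepertoireSample

__all__ = [
    "FormatError", "ReadReport", "read_airr", "read_trust4_report",
    "write_airr", "filter_complete", "read_sample_sheet",
]

#: markers in TRUST4 CDR3 amino-acid strings flagging non-productive chains
STOP_MARKER = "*"
OUT_OF_FRAME_MARKER = "_"
PARTIAL_MARKER = "?"

_TCR_PREFIXES = ("TRA", "TRB", "TRG", "TRD")


class FormatError(ValueError):
    """Input file does not conform to the expected table dialect."""


@dataclass
class ReadReport:
    """Per-file accounting of what the reader did with each row."""

    n_rows: int = 0                 # data rows seen in the file
    n_kept: int = 0                 # clonotypes after merging
    n_merged: int = 0               # rows folded into an existing key
    n_rejected: int = 0             # unclassifiable rows (no V and no C call)
    n_tcr_discarded: int = 0        # TCR-locus rows (TRUST4 only)
    discard_reasons: dict = field(default_factory=dict)


def _finalize(
    df: pd.DataFrame, sample_id: str, group: str, modality: str,
    report: ReadReport,
) -> tuple[RepertoireSample, ReadReport]:
    # reject records with neither a V nor a C call: unclassifiable
    classifiable = (df["v_call"] != "") | (df["c_call"] != "")
    report.n_rejected = int((~classifiable).sum())
    df = df[classifiable]
    sample = RepertoireSample.from_frame(df, sample_id, group, modality)
    report.n_kept = sample.n_clonotypes
    report.n_merged = len(df) - sample.n_clonotypes
    if sample.n_clonotypes == 0:
        warnings.warn(
            f"sample {sample_id!r}: no valid clonotype rows (empty repertoire)",
            stacklevel=3,
        )
    return sample, report


def read_airr(
    path, sample_id: str, group: str, modality: str = "bulk",
) -> tuple[RepertoireSample, ReadReport]:
    """Read an AIRR Rearrangement TSV into a repertoire sample.

    Requires ``junction``, ``v_call``, ``j_call``, ``c_call`` and one of
    ``duplicate_count``/``consensus_count``. ``cell_id``, ``junction_aa`` and
    ``d_call`` are used when present. Duplicate identity keys are merged by
    summing counts; rows with neither V nor C call are rejected and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("junction", "v_call", "j_call", "c_call"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory AIRR column {col!r}")
    count_col = next(
        (c for c in ("duplicate_count", "consensus_count") if c in raw.columns),
        None,
    )
    if count_col is None:
        raise FormatError(
            f"{path}: missing count column (duplicate_count or consensus_count)"
        )
    report = ReadReport(n_rows=len(raw))
    counts = pd.to_numeric(raw[count_col], errors="coerce")
    bad = counts.isna() | (counts < 1)
    if bad.any():
        report.discard_reasons["bad_count"] = int(bad.sum())
    raw = raw[~bad]
    df = pd.DataFrame({
        "cdr3_nt": raw["junction"],
        "cdr3_aa": raw.get("junction_aa", ""),
        "v_call": raw["v_call"],
        "d_call": raw.get("d_call", ""),
        "j_call": raw["j_call"],
        "c_call": raw["c_call"],
        "read_count": counts[~bad].astype(int),
        "cell_barcode": raw.get("cell_id", ""),
    })
    return _finalize(df, sample_id, group, modality, report)


def read_trust4_report(
    path, sample_id: str, group: str, modality: str = "bulk",
) -> tuple[RepertoireSample, ReadReport]:
    """Read a TRUST4 report TSV (``count frequency CDR3nt CDR3aa V D J C``).

    A leading ``#`` on the header is tolerated; ``*``/``.`` gene placeholders
    map to empty calls; TCR-locus rows (TRA/TRB/TRG/TRD) are filtered out and
    counted in the report.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw.columns = [c.lstrip("#").strip() for c in raw.columns]
    lower = {c.lower(): c for c in raw.columns}
    needed = ["count", "cdr3nt", "cdr3aa", "v", "d", "j", "c"]
    missing = [c for c in needed if c not in lower]
    if missing:
        raise FormatError(f"{path}: missing TRUST4 report column(s) {missing}")
    report = ReadReport(n_rows=len(raw))
    counts = pd.to_numeric(raw[lower["count"]], errors="coerce")
    nonint = counts.isna() | (counts != counts.round())
    if nonint.any():
        row = int(nonint.idxmax()) + 2  # 1-based, counting the header line
        raise FormatError(f"{path}: non-integer count field at line {row}")

    def genes(col: str) -> pd.Series:
        s = raw[lower[col]].str.strip()
        return s.where(~s.isin(["*", ".", ""]), "")

    df = pd.DataFrame({
        "cdr3_nt": raw[lower["cdr3nt"]],
        "cdr3_aa": raw[lower["cdr3aa"]],
        "v_call": genes("v"),
        "d_call": genes("d"),
        "j_call": genes("j"),
        "c_call": genes("c"),
        "read_count": counts.astype(int),
        "cell_barcode": raw[lower["cid"]] if "cid" in lower else "",
    })
    df["cdr3_nt"] = df["cdr3_nt"].where(~df["cdr3_nt"].isin(["*", "."]), "")
    is_tcr = (
        df["v_call"].str[:3].isin(_TCR_PREFIXES)
        | df["c_call"].str[:3].isin(_TCR_PREFIXES)
        | df["j_call"].str[:3].isin(_TCR_PREFIXES)
    )
    report.n_tcr_discarded = int(is_tcr.sum())
    df = df[~is_tcr]
    zero = df["read_count"] < 1
    if zero.any():
        report.discard_reasons["zero_count"] = int(zero.sum())
        df = df[~zero]
    return _finalize(df, sample_id, group, modality, report)


def write_airr(sample: RepertoireSample, path) -> None:
    """Write a sample as AIRR Rearrangement TSV (stable column order)."""
    df = sample.clonotypes
    out = pd.DataFrame({
        "sequence_id": [
            f"{sample.sample_id}_{i}" for i in range(len(df))
        ],
        "junction": df["cdr3_nt"].values,
        "junction_aa": df["cdr3_aa"].values,
        "v_call": df["v_call"].values,
        "d_call": df["d_call"].values,
        "j_call": df["j_call"].values,
        "c_call": df["c_call"].values,
        "duplicate_count": df["read_count"].values,
        "cell_id": df["cell_barcode"].values,
    })
    out.to_csv(path, sep="\t", index=False)


def filter_complete(
    sample: RepertoireSample,
) -> tuple[RepertoireSample, dict[str, int]]:
    """Drop non-productive clonotypes, tallying each discard reason.

    Retains records with a non-empty CDR3 nucleotide sequence whose amino-acid
    CDR3 contains no stop (``*``), out-of-frame (``_``) or partial (``?``)
    marker. Returns a new sample and a ``{reason: n}`` tally.
    """
    df = sample.clonotypes
    tally: dict[str, int] = {}
    no_cdr3 = df["cdr3_nt"] == ""
    stop = ~no_cdr3 & df["cdr3_aa"].str.contains(STOP_MARKER, regex=False)
    oof = ~no_cdr3 & ~stop & df["cdr3_aa"].str.contains(
        OUT_OF_FRAME_MARKER, regex=False
    )
    partial = (
        ~no_cdr3 & ~stop & ~oof
        & df["cdr3_aa"].str.contains(PARTIAL_MARKER, regex=False)
    )
    for reason, mask in [
        ("no_cdr3", no_cdr3), ("stop_codon", stop),
        ("out_of_frame", oof), ("partial", partial),
    ]:
        if mask.any():
            tally[reason] = int(mask.sum())
    keep = ~(no_cdr3 | stop | oof | partial)
    out = RepertoireSample(
        sample_id=sample.sample_id, group=sample.group,
        clonotypes=df[keep].reset_index(drop=True), modality=sample.modality,
    )
    return out, tally


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV mapping sample_id -> group (+ optional path)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in sample sheet")
    return sheet
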