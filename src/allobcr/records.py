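"""Domain types for clonotype records and the immunoglobulin chain hierarchy.

A clonotype is one assembled receptor chain: CDR3 sequence plus V/D/J/C gene
calls and a read count. Chains are organized in the fixed hierarchy

    total -> {heavy, light}
    heavy -> {IGHA, IGHD, IGHE, IGHG, IGHM}          (constant-region isotype)
    IGHG  -> {IGHG1, IGHG2, IGHG3, IGHG4}            (subclass)
    IGHA  -> {IGHA1, IGHA2}

IGHD/IGHM/IGHE have no subclass level. A heavy chain whose constant gene could
not be resolved still counts at the heavy level but carries no isotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCI = ("IGH", "IGK", "IGL")
ISOTYPES = ("IGHA", "IGHD", "IGHE", "IGHG", "IGHM")
SUBCLASSES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2")

#: hierarchy levels reported by summaries, in canonical order
LEVELS = ("total", "heavy", "light") + ISOTYPES + SUBCLASSES

#: parent of each non-root level (used for within-parent proportions)
LEVEL_PARENT = {
    "heavy": "total",
    "light": "total",
    **{iso: "heavy" for iso in ISOTYPES},
    "IGHG1": "IGHG", "IGHG2": "IGHG", "IGHG3": "IGHG", "IGHG4": "IGHG",
    "IGHA1": "IGHA", "IGHA2": "IGHA",
}

GROUP_LABELS = ("TCMR", "STA", "aABMR", "caABMR", "MIX", "other")

#: canonical column order of a clonotype frame
CLONOTYPE_COLUMNS = [
    "cdr3_nt", "cdr3_aa", "v_call", "d_call", "j_call", "c_call",
    "read_count", "cell_barcode",
    "locus", "chain_level", "isotype", "subclass",
]

#: columns that define clonotype identity (cell_barcode added in single-cell mode)
IDENTITY_KEY = ["cdr3_nt", "v_call", "j_call", "c_call"]


class ClassificationError(ValueError):
    """Raised when a record carries neither a V nor a C gene call."""


def trim_allele(name: str) -> str:
    """Strip the IMGT allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return name.split("*", 1)[0].strip()


@dataclass(frozen=True)
class ChainClass:
    """Position of one receptor chain in the immunoglobulin hierarchy."""

    locus: str          # IGH, IGK or IGL
    chain_level: str    # "heavy" or "light"
    isotype: str        # IGHA/IGHD/IGHE/IGHG/IGHM or "" when unresolved
    subclass: str       # IGHG1-4 / IGHA1-2 or ""


def classify_chain(v_call: str, c_call: str) -> ChainClass:
    """Classify a chain from its V and constant gene calls.

    The locus comes from the leading three characters of the constant call if
    present, else of the V call. Isotype and subclass are resolved from the
    allele-trimmed constant gene of heavy chains only; a heavy chain with an
    unresolvable constant region gets isotype ``""`` and still counts at the
    chain level.
    """
    v = trim_allele(v_call or "")
    c = trim_allele(c_call or "")
    if not v and not c:
        raise ClassificationError("record has neither v_call nor c_call")
    locus = (c or v)[:3]
    if locus not in LOCI:
        raise ClassificationError(f"unrecognized locus prefix {locus!r}")
    if locus != "IGH":
        return ChainClass(locus, "light", "", "")
    isotype = c[:4] if c[:4] in ISOTYPES else ""
    subclass = c if c in SUBCLASSES else ""
    return ChainClass("IGH", "heavy", isotype, subclass)


def classify_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_chain` over a clonotype frame.

    Adds/overwrites the ``locus``, ``chain_level``, ``isotype`` and ``subclass``
    columns. Rows with neither call must have been rejected upstream.
    """
    v = df["v_call"].fillna("").str.split("*").str[0]
    c = df["c_call"].fillna("").str.split("*").str[0]
    locus = c.where(c != "", v).str[:3]
    bad = ~locus.isin(LOCI)
    if bad.any():
        raise ClassificationError(
            f"{int(bad.sum())} records with unrecognized locus "
            f"(e.g. {locus[bad].iloc[0]!r})"
        )
    out = df.copy()
    out["locus"] = locus
    out["chain_level"] = np.where(locus == "IGH", "heavy", "light")
    iso = c.str[:4].where(c.str[:4].isin(ISOTYPES) & (locus == "IGH"), "")
    out["isotype"] = iso
    out["subclass"] = c.where(c.isin(SUBCLASSES) & (locus == "IGH"), "")
    return out


@dataclass(frozen=True)
class ClonotypeRecord:
    """One assembled receptor chain with gene calls, CDR3 and abundance."""

    sample_id: str
    cdr3_nt: str
    cdr3_aa: str = ""
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    c_call: str = ""
    read_count: int = 1
    cell_barcode: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if not (self.v_call or self.c_call):
            raise ClassificationError(
                "unclassifiable record: both v_call and c_call empty"
            )

    @property
    def chain(self) -> ChainClass:
        return classify_chain(self.v_call, self.c_call)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "cdr3_nt": pd.Series(dtype=str), "cdr3_aa": pd.Series(dtype=str),
        "v_call": pd.Series(dtype=str), "d_call": pd.Series(dtype=str),
        "j_call": pd.Series(dtype=str), "c_call": pd.Series(dtype=str),
        "read_count": pd.Series(dtype=np.int64),
        "cell_barcode": pd.Series(dtype=str),
        "locus": pd.Series(dtype=str), "chain_level": pd.Series(dtype=str),
        "isotype": pd.Series(dtype=str), "subclass": pd.Series(dtype=str),
    })


@dataclass
class RepertoireSample:
    """All clonotypes of one biopsy sample with its clinical group label.

    ``clonotypes`` is a frame with :data:`CLONOTYPE_COLUMNS`; one row per
    distinct identity key (duplicates are merged at construction by summing
    read counts).
    """

    sample_id: str
    group: str
    clonotypes: pd.DataFrame = field(default_factory=_empty_frame)
    modality: str = "bulk"  # "bulk" | "single_cell"

    @property
    def identity_key(self) -> list[str]:
        key = list(IDENTITY_KEY)
        if self.modality == "single_cell":
            key.append("cell_barcode")
        return key

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["read_count"].sum())

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sample_id: str,
        group: str,
        modality: str = "bulk",
    ) -> "RepertoireSample":
        """Build a sample from a raw clonotype frame.

        Classifies every row, merges duplicate identity keys by summing
        read counts, and normalizes the column order.
        """
        sample = cls(sample_id=sample_id, group=group, modality=modality)
        if frame.empty:
            return sample
        df = frame.copy()
        for col in ("cdr3_nt", "cdr3_aa", "v_call", "d_call", "j_call",
                    "c_call", "cell_barcode"):
            if col not in df:
                df[col] = ""
            df[col] = df[col].fillna("").astype(str)
        df["read_count"] = df["read_count"].astype(np.int64)
        if (df["read_count"] < 1).any():
            raise ValueError("read_count must be >= 1 for every record")
        df = classify_frame(df)
        key = sample.identity_key
        merged = (
            df.groupby(key, as_index=False, sort=False)
            .agg({
                "cdr3_aa": "first", "d_call": "first", "read_count": "sum",
                "cell_barcode": "first",
                "locus": "first", "chain_level": "first",
                "isotype": "first", "subclass": "first",
            })
        )
        sample.clonotypes = merged[CLONOTYPE_COLUMNS].reset_index(drop=True)
        return sample

    def records(self):
        """Iterate clonotypes as :class:`ClonotypeRecord` objects."""
        for row in self.clonotypes.itertuples(index=False):
            yield ClonotypeRecord(
                sample_id=self.sample_id, cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3_aa, v_call=row.v_call, d_call=row.d_call,
                j_call=row.j_call, c_call=row.c_call,
                read_count=int(row.read_count), cell_barcode=row.cell_barcode,
            )
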