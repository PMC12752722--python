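import numpy as np
import pandas as pd
import pytest

from allobcr.records import RepertoireSample


def make_sample(rows, sample_id="S1", group="TCMR", modality="bulk"):
    """Build a RepertoireSample from (cdr3_nt, v, j, c, count[, barcode]) rows."""
    recs = []
    for row in rows:
        cdr3, v, j, c, count = row[:5]
        barcode = row[5] if len(row) > 5 else ""
        recs.append({
            "cdr3_nt": cdr3, "cdr3_aa": "C" + "A" * (len(cdr3) // 3 - 2) + "W",
            "v_call": v, "d_call": "", "j_call": j, "c_call": c,
            "read_count": count, "cell_barcode": barcode,
        })
    return RepertoireSample.from_frame(
        pd.DataFrame(recs), sample_id, group, modality
    )


@pytest.fixture
def heavy_light_sample():
    """2 IGHG1 clonotypes (reads 5, 5) + 3 IGKC clonotypes (reads 1, 1, 1)."""
    return make_sample([
        ("TGTGCATGG", "IGHV3-23*01", "IGHJ4*01", "IGHG1", 5),
        ("TGTGCCTGG", "IGHV3-30*01", "IGHJ4*01", "IGHG1", 5),
        ("TGTAAATGG", "IGKV1-39*01", "IGKJ1*01", "IGKC", 1),
        ("TGTAAGTGG", "IGKV1-39*01", "IGKJ2*01", "IGKC", 1),
        ("TGTAACTGG", "IGKV3-20*01", "IGKJ1*01", "IGKC", 1),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
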