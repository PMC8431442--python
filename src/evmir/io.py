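"""Readers and writers for the pipeline's plain-text table formats.

Count matrices are tab-separated with the miRNA id in the first column and
one column per specimen; specimen metadata is comma-separated with columns
specimen_id, diagnosis, metastasis, ca199_u_ml, cea_ng_ml, os_days,
os_event (and optionally split = train/test).  All tables are UTF-8 with a
dot decimal separator.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIAGNOSIS_LABELS = {"PDAC", "CP", "healthy"}
METASTASIS_LABELS = {"M0", "M1"}

__all__ = ["read_counts", "write_counts", "read_metadata", "write_metadata",
           "write_truth", "read_truth"]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV count matrix (rows = miRNAs, columns = specimens)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate miRNA id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate specimen id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed count {cell!r} at miRNA {df.index[i]!r}, "
                    f"specimen {col!r} in {path}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative count at miRNA {df.index[i]!r}, specimen {col!r} in {path}"
                )
            values[i, j] = v
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    log.info("read counts: %d miRNAs x %d specimens from %s", *out.shape, path)
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def read_metadata(path: str | Path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate the specimen metadata CSV.

    Diagnosis labels outside {PDAC, CP, healthy} are rejected; optional
    fields stay missing (NaN) rather than being imputed.  When ``counts`` is
    given, every count-matrix specimen must be present in the metadata.
    """
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns or "diagnosis" not in df.columns:
        raise ValueError(f"{path}: metadata needs specimen_id and diagnosis columns")
    df = df.set_index("specimen_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate specimen_id")
    bad = set(df["diagnosis"].unique()) - DIAGNOSIS_LABELS
    if bad:
        raise ValueError(f"{path}: unknown diagnosis label(s) {sorted(bad)}")
    if "metastasis" in df.columns:
        bad = set(df["metastasis"].dropna().unique()) - METASTASIS_LABELS
        if bad:
            raise ValueError(f"{path}: unknown metastasis label(s) {sorted(bad)}")
    for col in ("metastasis", "ca199_u_ml", "cea_ng_ml", "os_days", "os_event", "split"):
        if col not in df.columns:
            df[col] = pd.NA
    if df["ca199_u_ml"].isna().any():
        n = int(df["ca199_u_ml"].isna().sum())
        log.warning("%s: %d specimens missing CA19-9", path, n)
    df["os_event"] = df["os_event"].map(
        {1: True, 0: False, "1": True, "0": False, True: True, False: False,
         "True": True, "False": False}
    ).astype("boolean")
    if counts is not None:
        missing = [s for s in counts.columns if s not in df.index]
        if missing:
            raise ValueError(f"{path}: specimens in counts but not metadata: {missing[:5]}")
    return df


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    if "os_event" in out.columns:
        out["os_event"] = out["os_event"].map({True: 1, False: 0})
    out.to_csv(path, index_label="specimen_id")


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
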