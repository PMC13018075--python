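"""NONMEM-dialect CSV reading/writing and validation.

Column semantics follow the usual NONMEM event-record conventions: one row
per dose (EVID=1, AMT>0, DV missing) or observation (EVID=0, MDV=0, DV
present); CMT distinguishes the record stream (1 depot dose, 2 drug
concentration, 3 IGF-1, 4 growth velocity).  Missing DV is written as ``.``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_nonmem_csv", "write_nonmem_csv", "validate_nonmem", "kind_of", "NonmemFormatError"]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")
CMT_KINDS = {1: "dose", 2: "pk", 3: "igf1", 4: "gv"}


class NonmemFormatError(ValueError):
    """A dataset violates the NONMEM dialect rules."""


def validate_nonmem(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise NonmemFormatError(f"missing required columns: {missing}")
    if "MDV" not in df.columns:
        df = df.copy()
        df["MDV"] = np.where(df["DV"].isna(), 1, 0)
    bad = df[(df["EVID"] == 1) & df["DV"].notna()]
    if len(bad):
        rows = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
        raise NonmemFormatError(f"dose rows (EVID=1) must have missing DV; see file rows {rows}")
    for sid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            row = int(sub.index[np.argmax(np.diff(t) < 0) + 1]) + 2
            raise NonmemFormatError(
                f"non-monotone TIME within subject {sid!r} at file row {row}"
            )
    return df


def read_nonmem_csv(path) -> pd.DataFrame:
    """Read and validate a NONMEM-style CSV; ``.`` parses as missing DV."""
    df = pd.read_csv(path, na_values=["."], float_precision="round_trip")
    return validate_nonmem(df)


def write_nonmem_csv(df: pd.DataFrame, path) -> None:
    """Write a NONMEM-style CSV (missing DV as ``.``); round-trips exactly."""
    validate_nonmem(df).to_csv(path, index=False, na_rep=".")


def kind_of(row) -> str:
    """Record kind of one row: 'dose', 'pk', 'igf1' or 'gv'."""
    if row["EVID"] == 1:
        return "dose"
    return CMT_KINDS.get(int(row.get("CMT", 2)), "pk")
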