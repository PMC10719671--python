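"""Canonical flat-file schemas for interview records and criterion profiles.

Interview CSV (one row per twin): ``pair_id, twin_order, zygosity_group,
sex, item_01..item_14, somatic_01..somatic_14, syndrome1, syndrome2`` where
the syndrome columns hold semicolon-joined item indices (1-based in the
file, matching the item column numbering; empty allowed).

Profile CSV (one row per twin): ``pair_id, twin_order, zygosity_group``
followed by ``in_*`` and ``out_*`` status columns; statuses are 0/1 with an
empty cell for an unknown (censored) status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import InterviewRecord
from .definitions import CRITERIA, N_ITEMS, ZYGOSITY_GROUPS

__all__ = [
    "SchemaError",
    "interview_columns",
    "records_to_frame",
    "frame_to_records",
    "write_interviews",
    "read_interviews",
    "write_profiles",
    "read_profiles",
]


class SchemaError(ValueError):
    """Raised with row/column context when a flat file violates the schema."""


def interview_columns() -> list[str]:
    return (
        ["pair_id", "twin_order", "zygosity_group", "sex"]
        + [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
        + [f"somatic_{i:02d}" for i in range(1, N_ITEMS + 1)]
        + ["syndrome1", "syndrome2"]
    )


def records_to_frame(records: list[InterviewRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "pair_id": r.pair_id,
            "twin_order": r.twin_order,
            "zygosity_group": r.zygosity_group,
            "sex": r.sex,
        }
        for i in range(N_ITEMS):
            row[f"item_{i + 1:02d}"] = int(r.items[i])
            row[f"somatic_{i + 1:02d}"] = int(r.somatic_flags[i])
        for s_i in (0, 1):
            key = f"syndrome{s_i + 1}"
            if s_i < len(r.syndromes):
                row[key] = ";".join(str(i + 1) for i in sorted(r.syndromes[s_i]))
            else:
                row[key] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=interview_columns())


def frame_to_records(df: pd.DataFrame) -> list[InterviewRecord]:
    expected = interview_columns()
    for col in expected:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            items = np.array(
                [int(row[f"item_{i:02d}"]) for i in range(1, N_ITEMS + 1)]
            )
            somatic = np.array(
                [int(row[f"somatic_{i:02d}"]) for i in range(1, N_ITEMS + 1)]
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {pos}: non-binary item/somatic value ({exc})")
        zyg = str(row["zygosity_group"])
        if zyg not in ZYGOSITY_GROUPS:
            raise SchemaError(
                f"row {pos}, column 'zygosity_group': unknown group {zyg!r}"
            )
        syndromes = []
        for key in ("syndrome1", "syndrome2"):
            val = row[key]
            if pd.isna(val) or str(val).strip() == "":
                continue
            try:
                idx = {int(tok) - 1 for tok in str(val).split(";")}
            except ValueError:
                raise SchemaError(f"row {pos}, column {key!r}: malformed index list {val!r}")
            if not idx <= set(range(N_ITEMS)):
                raise SchemaError(f"row {pos}, column {key!r}: item index out of range")
            syndromes.append(idx)
        try:
            records.append(
                InterviewRecord(
                    pair_id=str(row["pair_id"]),
                    twin_order=int(row["twin_order"]),
                    zygosity_group=zyg,
                    sex=str(row["sex"]),
                    items=items,
                    somatic_flags=somatic,
                    syndromes=syndromes,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {pos}: {exc}")
    return records


def write_interviews(records: list[InterviewRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_interviews(path) -> list[InterviewRecord]:
    df = pd.read_csv(path, dtype={"syndrome1": str, "syndrome2": str})
    return frame_to_records(df)


def write_profiles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    status_cols = [f"{m}_{c}" for m in ("in", "out") for c in CRITERIA]
    for pos_col in ("pair_id", "twin_order", "zygosity_group"):
        if pos_col not in df.columns:
            raise SchemaError(f"missing column {pos_col!r}")
    for col in status_cols:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
        s = pd.to_numeric(df[col], errors="coerce")
        bad = s.notna() & ~s.isin([0, 1])
        if bad.any():
            raise SchemaError(
                f"row {int(np.flatnonzero(bad)[0]) + 1}, column {col!r}: "
                "status must be 0, 1 or empty"
            )
        df[col] = s.astype("Int64")
    return df
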