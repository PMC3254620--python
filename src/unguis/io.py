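"""Delimited-text readers/writers, reports, and run manifests.

Tabular inputs are UTF-8 delimited text (comma by default, tab accepted)
with a header row.  Validation errors carry 1-based data-row numbers and
the offending column.  Every analysis run can emit a manifest (inputs,
seeds, configuration) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, UnguisError
from .records import (
    FOOT_ELEMENTS,
    PHALANX_LINEAR_FIELDS,
    FootRecord,
    PhalanxRecord,
)

_PHALANX_META = ("specimen_id", "taxon", "digit", "unguis_group")
_FOOT_META = ("individual_id", "taxon", "dfa_group", "ratio_group", "gradistic_group")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       skip_blank_lines=True)


def _num(value, row: int, col: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "na", "?", "-"):
        return None
    try:
        return float(s)
    except ValueError:
        raise InvalidMeasurementError(col, f"non-numeric cell {s!r} in row {row}") from None


def read_phalanx_measurements(path) -> list[PhalanxRecord]:
    """Read distal-phalanx measurements; header must include the nine
    measurement columns (BH..FSA) plus specimen_id/taxon/digit/unguis_group."""
    df = _read_table(path)
    required = set(PHALANX_LINEAR_FIELDS) | {"FSA", "specimen_id"}
    unknown = set(df.columns) - required - set(_PHALANX_META)
    if unknown:
        raise UnguisError(f"unknown column(s): {sorted(unknown)}")
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise UnguisError(f"missing column(s): {sorted(missing_cols)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            digit = row.get("digit")
            records.append(PhalanxRecord(
                specimen_id=str(row["specimen_id"]),
                taxon=str(row.get("taxon") or ""),
                digit=int(float(digit)) if digit not in (None, "", "?") and not pd.isna(digit) else None,
                unguis_group=str(row.get("unguis_group") or "unassigned"),
                **{f: _num(row.get(f), i, f) for f in PHALANX_LINEAR_FIELDS},
                FSA=_num(row.get("FSA"), i, "FSA"),
            ))
        except InvalidMeasurementError as exc:
            raise InvalidMeasurementError(exc.field, f"row {i}: {exc}") from None
    return records


def read_foot_measurements(path) -> list[FootRecord]:
    """Read pedal element lengths (mt1..mt5, pp1..pp5, ip2, ip3, ip5)."""
    df = _read_table(path)
    if "individual_id" not in df.columns:
        raise UnguisError("missing column 'individual_id'")
    unknown = set(df.columns) - set(FOOT_ELEMENTS) - set(_FOOT_META)
    if unknown:
        raise UnguisError(f"unknown column(s): {sorted(unknown)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()

        def _opt(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) or str(v).strip() == "" else str(v)

        try:
            records.append(FootRecord(
                individual_id=str(row["individual_id"]),
                taxon=str(row.get("taxon") or ""),
                dfa_group=_opt("dfa_group"),
                ratio_group=_opt("ratio_group"),
                gradistic_group=_opt("gradistic_group"),
                **{f: _num(row.get(f), i, f) for f in FOOT_ELEMENTS},
            ))
        except InvalidMeasurementError as exc:
            raise InvalidMeasurementError(exc.field, f"row {i}: {exc}") from None
    return records


def write_phalanx_measurements(records: list[PhalanxRecord], path, sep=",") -> None:
    rows = [asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_foot_measurements(records: list[FootRecord], path, sep=",") -> None:
    rows = [asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def format_parsimony_statistics(result) -> str:
    """One-line tree-statistics report: 'TL = .., CI = .., HI = .., ...'."""
    if not result.mp_trees:
        raise AssertionError("a parsimony result must contain >= 1 MP tree")
    return (
        f"TL = {result.TL}, CI = {result.CI:.4f}, HI = {result.HI:.4f}, "
        f"RI = {result.RI:.4f}, RC = {result.RC:.4f}"
    )


def classification_table(report, decimals: int = 2) -> pd.DataFrame:
    """Display form of a fossil classification report (t rounded to 2 dp,
    as published tables print them; full precision stays on the report)."""
    df = report.table.reset_index()
    df["t"] = df["t"].round(decimals)
    return df


def run_manifest(
    analysis: str, inputs: dict, seed: int | None = None, config: dict | None = None
) -> dict:
    """Reproducibility manifest for one analysis run."""
    import unguis

    return {
        "analysis": analysis,
        "package_version": unguis.__version__,
        "inputs": inputs,
        "seed": seed,
        "config": config or {},
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
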