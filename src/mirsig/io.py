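"""Reading and writing the pipeline's tabular artifacts.

Conventions
-----------
Ct tables are CSV/TSV with samples in rows; the first column is ``sample_id``,
optional metadata columns (``cohort``, ``timepoint``, ``dose_gy``,
``excluded``, ``exclusion_reason``) follow, and every remaining column is one
miRNA assay.  Missing measurements may be blank, the instrument sentinel
``"Undetermined"``, or a Ct at the 40-cycle ceiling (a 40-cycle run cannot
yield an informative Ct there); all three parse to missing.  Decimal points
only — parsing is locale-independent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_CONTROL_MAP, META_COLUMNS, CtMatrix, validate_clinical

logger = logging.getLogger(__name__)

#: tokens an instrument export may use for "no amplification"
MISSING_SENTINELS = {"", "undetermined", "na", "nan", "n/a"}
CT_CEILING = 40.0


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _parse_ct_cell(raw, row: str, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.lower() in MISSING_SENTINELS:
        return np.nan
    try:
        value = float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric Ct value {raw!r} at sample {row!r}, assay {col!r}"
        ) from None
    return np.nan if value >= CT_CEILING else value


def read_ct_table(
    path: str | Path,
    control_map: Mapping[str, str] | None = None,
    cohort: str = "targeted",
    timepoint: str = "D1",
) -> CtMatrix:
    """Read a wide-format Ct table into a :class:`CtMatrix`.

    ``control_map`` maps roles (reference / hemolysis / spikein) to assay
    column names; roles whose column is absent are flagged (``controls[role]
    is None``) so downstream QC degrades gracefully instead of failing.
    ``cohort``/``timepoint`` are defaults used when the file carries no
    metadata columns.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    first = raw.columns[0]
    if raw[first].duplicated().any():
        dupes = raw.loc[raw[first].duplicated(), first].tolist()
        raise ValueError(f"duplicate sample ids in {path.name}: {dupes}")
    if pd.Index(raw.columns).duplicated().any():
        dupes = pd.Index(raw.columns)[pd.Index(raw.columns).duplicated()].tolist()
        raise ValueError(f"duplicate assay ids in {path.name}: {dupes}")
    raw = raw.set_index(first)
    raw.index.name = "sample_id"

    meta_cols = [c for c in META_COLUMNS[1:] if c in raw.columns]
    meta = pd.DataFrame(index=raw.index)
    meta["cohort"] = raw["cohort"] if "cohort" in meta_cols else cohort
    meta["timepoint"] = raw["timepoint"] if "timepoint" in meta_cols else timepoint
    meta["dose_gy"] = (
        pd.to_numeric(raw["dose_gy"]).astype(float) if "dose_gy" in meta_cols else np.nan
    )
    meta["excluded"] = (
        raw["excluded"].str.lower().isin({"true", "1"}) if "excluded" in meta_cols else False
    )
    meta["exclusion_reason"] = (
        raw["exclusion_reason"] if "exclusion_reason" in meta_cols else ""
    )

    assay_cols = [c for c in raw.columns if c not in meta_cols]
    n_missing = 0
    values = pd.DataFrame(index=raw.index, columns=assay_cols, dtype=float)
    for col in assay_cols:
        parsed = [
            _parse_ct_cell(v, sid, col) for sid, v in zip(raw.index, raw[col])
        ]
        values[col] = parsed
        n_missing += int(np.isnan(parsed).sum())
    logger.info("read %s: %d samples x %d assays, %d missing Ct",
                path.name, values.shape[0], values.shape[1], n_missing)

    control_map = dict(control_map or DEFAULT_CONTROL_MAP)
    ct = CtMatrix(values, meta, control_map)
    for role, assay in control_map.items():
        if ct.controls.get(role) is None:
            logger.warning("control role %r (%s) absent from %s", role, assay, path.name)
    return ct


def write_ct_table(ct: CtMatrix, path: str | Path) -> None:
    """Write a CtMatrix (values + metadata columns) as CSV/TSV; round-trips exactly."""
    path = Path(path)
    out = ct.meta.copy()
    out = pd.concat([out, ct.values], axis=1)
    out.to_csv(path, sep=_sep_for(path), index_label="sample_id", float_format="%.10g")


def read_clinical_table(path: str | Path, timepoint: str | None = None) -> pd.DataFrame:
    """Read a clinical table (first column sample_id, numeric fields after)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    non_numeric = [c for c in df.columns if c != "dose_gy" and not
                   pd.api.types.is_numeric_dtype(df[c])]
    for col in non_numeric:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return validate_clinical(df, timepoint)


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index_label="sample_id", float_format="%.10g")


def write_signature_report(model, path: str | Path) -> None:
    """Write the selected-signature table (component, miRNA, stability, loading).

    Row order is deterministic: component ascending, stability descending,
    then assay name — matching how signature tables are conventionally read.
    """
    sig = getattr(model, "signature", None)
    if sig is None:
        raise ValueError("model has no signature; fit it (and compute stability) first")
    sig = sig.sort_values(
        by=["component", "stability", "miRNA"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    sig.to_csv(Path(path), index=False, float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
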