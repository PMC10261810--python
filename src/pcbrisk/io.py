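"""Reading and writing the standard sample CSV and YAML configs.

The sample CSV has the header
``sample_id,product,brand,PCB28,PCB52,PCB101,PCB138,PCB153,PCB180`` with
concentrations in ng/g fat, UTF-8, "." decimal separator. Left-censored
results are encoded as the literal cell ``<LOD``; on reading they become
NaN plus a ``<congener>_censored`` flag column, to be substituted via
:func:`pcbrisk.qc.substitute_censored`. Lines starting with ``#`` are
treated as provenance comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .congeners import BRANDS, CONGENER_NAMES, PRODUCTS
from .errors import SchemaError
from .qc import substitute_censored

__all__ = [
    "read_samples",
    "write_samples",
    "apply_censoring",
    "load_yaml",
    "save_yaml",
    "CENSORED_TOKEN",
]

CENSORED_TOKEN = "<LOD"

_META_COLUMNS = ("sample_id", "product", "brand")


def read_samples(path: str | Path | _io.StringIO) -> pd.DataFrame:
    """Read and validate a sample table.

    Returns a frame with the canonical columns plus one boolean
    ``<congener>_censored`` column per congener; censored cells hold NaN
    until substitution. Raises :class:`SchemaError` naming the offending
    row/column for missing columns, negative values, or unknown
    product/brand labels.
    """
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in (*_META_COLUMNS, *CONGENER_NAMES) if c not in raw.columns]
    if missing:
        raise SchemaError(f"sample file missing column(s) {missing}")

    out = raw[list(_META_COLUMNS)].copy()
    bad_product = ~out["product"].isin(PRODUCTS)
    if bad_product.any():
        row = int(np.flatnonzero(bad_product)[0])
        raise SchemaError(
            f"row {row}: unknown product {out['product'].iloc[row]!r} "
            f"(column 'product'; expected one of {PRODUCTS})"
        )
    bad_brand = ~(out["brand"].isin(BRANDS) | (out["brand"] == ""))
    if bad_brand.any():
        row = int(np.flatnonzero(bad_brand)[0])
        raise SchemaError(
            f"row {row}: unknown brand {out['brand'].iloc[row]!r} "
            f"(column 'brand'; expected A-E or empty)"
        )

    for name in CONGENER_NAMES:
        col = raw[name].str.strip()
        censored = col.str.upper() == CENSORED_TOKEN.upper()
        numeric = pd.to_numeric(col.mask(censored), errors="coerce")
        bad = numeric.isna() & ~censored
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"row {row}, column {name!r}: unparseable value {col.iloc[row]!r}"
            )
        neg = numeric < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise SchemaError(
                f"row {row}, column {name!r}: negative concentration {numeric.iloc[row]}"
            )
        out[name] = numeric.astype(float)
        out[f"{name}_censored"] = censored.to_numpy()
    return out


def write_samples(
    records: pd.DataFrame,
    path: str | Path | _io.StringIO,
    provenance: str | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write a sample table in the standard CSV layout.

    Censored entries (per ``<congener>_censored`` flags, if present) are
    written as the ``<LOD`` token. An optional provenance string is emitted
    as a leading ``#`` comment line.
    """
    cols = [*_META_COLUMNS, *CONGENER_NAMES]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise SchemaError(f"records missing column(s) {missing}")
    body = records[cols].copy()
    for name in CONGENER_NAMES:
        flag = f"{name}_censored"
        formatted = body[name].map(lambda v: float_format % v if pd.notna(v) else "")
        if flag in records.columns:
            formatted = formatted.mask(records[flag].astype(bool), CENSORED_TOKEN)
        body[name] = formatted

    def _dump(handle) -> None:
        if provenance:
            handle.write(f"# {provenance}\n")
        body.to_csv(handle, index=False)

    if isinstance(path, _io.StringIO):
        _dump(path)
    else:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            _dump(handle)


def apply_censoring(
    records: pd.DataFrame,
    lod: Mapping[str, float],
    loq: Mapping[str, float] | None = None,
    rule: str = "half_lod",
) -> pd.DataFrame:
    """Substitute censored concentrations per congener-specific LODs."""
    out = records.copy()
    for name in CONGENER_NAMES:
        flag = f"{name}_censored"
        if flag not in out.columns or not out[flag].any():
            continue
        vals = out[name].fillna(0.0).to_numpy()
        out[name] = substitute_censored(
            vals,
            out[flag].to_numpy(),
            lod=float(lod[name]),
            loq=float(loq[name]) if loq is not None else None,
            rule=rule,
        )
    return out


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return data


def save_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(dict(data), handle, sort_keys=True)
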