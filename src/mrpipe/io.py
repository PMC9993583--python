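"""Reading, validating and writing GWAS summary statistics.

The on-disk dialect is a tab-delimited UTF-8 table with a header row,
'.' decimal separator, and missing values written as empty fields or
``NA``.  The canonical column names are those in :data:`CANONICAL_COLUMNS`;
arbitrary source headers are supported through a ``column_map``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: Columns that must be resolvable by the column map.
MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

_NUMERIC = ["pos", "eaf", "beta", "se", "pvalue", "n"]


class ColumnMapError(KeyError):
    """A mandatory summary-statistic column could not be resolved."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


def validate_summary_stats(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Validate a canonical-column summary-stat table row by row.

    Rows violating the per-record invariants (positive SE, p-value in
    (0, 1], EAF in [0, 1] when present, distinct alleles, non-missing
    mandatory fields, unique SNP id) are dropped, each with a logged
    reason.  Returns ``(valid_rows, exclusions)`` where exclusions are
    ``(snp_id, reason)`` pairs; row order is preserved.
    """
    df = df.copy()
    reasons: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)

    def _drop(mask: np.ndarray, reason: str) -> None:
        mask = mask & keep
        for sid in df.loc[mask, "snp_id"].astype(str):
            reasons.append((sid, reason))
        keep[np.asarray(mask)] = False

    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    def _to_float(x):
        # float() round-trips repr-formatted values exactly
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    for col in _NUMERIC:
        if col in df:
            df[col] = df[col].map(_to_float).astype(float)
        else:
            df[col] = np.nan

    _drop(df[["beta", "se", "pvalue"]].isna().any(axis=1).to_numpy(), "missing mandatory value")
    _drop((df["se"] <= 0).fillna(True).to_numpy(), "nonpositive SE")
    _drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)).fillna(False).to_numpy(), "pvalue outside (0,1]")
    _drop((~df["eaf"].isna() & ((df["eaf"] < 0) | (df["eaf"] > 1))).to_numpy(), "eaf outside [0,1]")
    _drop((df["effect_allele"] == df["other_allele"]).to_numpy(), "identical alleles")
    _drop(df["snp_id"].duplicated(keep="first").to_numpy(), "duplicate snp_id")

    for sid, why in reasons:
        logger.info("dropped %s: %s", sid, why)
    out = df.loc[keep, CANONICAL_COLUMNS].reset_index(drop=True)
    for col in ("pos", "n"):  # keep genomic coordinates and sizes integral
        v = out[col]
        present = v.notna()
        if present.any() and np.all(np.mod(v[present], 1) == 0):
            out[col] = v.astype("Int64")
    return out, reasons


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab- or comma-delimited summary-statistic table.

    Parameters
    ----------
    path
        Input file with a header row.
    column_map
        Mapping from canonical names (:data:`CANONICAL_COLUMNS`) to the
        header names used in the file.  Omitted keys default to the
        canonical name itself.

    Returns
    -------
    A validated :class:`pandas.DataFrame` with canonical columns.  Rows
    failing the record invariants are dropped and logged.  The table
    carries the exclusion list in ``df.attrs["exclusions"]``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, na_values=["", "NA"], dtype=str,
                      float_precision="round_trip")
    if raw.empty:
        raise EmptyInputError(f"no data rows in {path}")

    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ColumnMapError(f"mandatory column {canon!r} (source header {src!r}) not found in {path}")
    df = raw.rename(columns=rename)
    for canon in CANONICAL_COLUMNS:
        if canon not in df:
            df[canon] = np.nan
    df = df[CANONICAL_COLUMNS]
    if "chrom" in df:
        df["chrom"] = df["chrom"].astype("string").fillna("").astype(str)
    out, exclusions = validate_summary_stats(df)
    out.attrs["exclusions"] = exclusions
    return out


def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical summary-stat table as tab-delimited text.

    Inverse of :func:`read_summary_stats` on validated tables: a
    write/read round trip is the identity.
    """
    df = records.copy()
    for canon in CANONICAL_COLUMNS:
        if canon not in df:
            df[canon] = np.nan
    df = df[CANONICAL_COLUMNS]
    # %r formatting of floats keeps the round trip exact
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=lambda x: repr(float(x)))


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r² matrix stored as TSV with snp_id header row and column."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if list(m.index) != list(m.columns):
        raise ValueError("LD matrix row and column snp_ids differ")
    return m


def write_ld_matrix(r2: pd.DataFrame, path: str | Path) -> None:
    r2.to_csv(path, sep="\t", index=True)
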