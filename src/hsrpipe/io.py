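"""Readers and writers for the pipeline's table formats.

TSV is the canonical interchange dialect (tab-separated, '.' decimal,
UTF-8, missing values written as ``NA``); CSV is accepted on read.
Numeric output uses 12 significant digits so write/read round-trips
preserve values.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .matrix import ExpressionMatrix
from .proteomics import FLAG_COLUMNS, ProteinTable

log = logging.getLogger(__name__)

NA_REP = "NA"
FLOAT_FORMAT = "%.12g"

#: Default MaxQuant proteinGroups column conventions.
MAXQUANT_FLAGS = {
    "Potential contaminant": "contaminant",
    "Reverse": "reverse",
    "Only identified by site": "only_identified_by_site",
}
LFQ_PREFIX = "LFQ intensity "


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples table (first column = gene id, header =
    sample ids)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         na_values=[NA_REP])
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse expression table {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene id(s) in {path}: {dups[:5]}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]].tolist()
    if non_numeric:
        for col in non_numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"non-numeric cell in {path}, column {col!r}, "
                    f"row {bad[0]!r}")
            df[col] = coerced
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path), na_rep=NA_REP,
                         float_format=FLOAT_FORMAT)


def read_sample_meta(path) -> pd.DataFrame:
    """Read atlas sample annotation: columns sample, region[, stage]."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample" not in df.columns or "region" not in df.columns:
        raise ParseError(
            f"{path}: sample metadata needs 'sample' and 'region' columns")
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in metadata")
    return df.set_index("sample")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index_label="sample")


def read_gmt(path) -> dict:
    """Read a GMT gene-set file into {name: set of members}.

    Each line: set name, description, then one or more members, all
    tab-separated. Duplicate members within a set are stored once (with
    a warning); an empty file yields an empty collection (warning).
    """
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members)")
            name = fields[0]
            members = [m for m in fields[2:] if m]
            if len(set(members)) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} "
                    f"stored once", stacklevel=2)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = set(members)
    if not sets:
        warnings.warn(f"{path}: empty gene-set collection", stacklevel=2)
    return sets


def write_gmt(sets: dict, path, description: str = NA_REP) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_protein_groups(path, design: dict | pd.Series,
                        lfq_prefix: str = LFQ_PREFIX,
                        flag_columns: dict | None = None) -> ProteinTable:
    """Read a MaxQuant proteinGroups-style TSV into a ProteinTable.

    ``design`` maps sample name (as it appears after ``lfq_prefix`` in
    the intensity headers) to its group label. Flag columns marked with
    '+' are translated to booleans; zeros in intensities become missing.
    """
    flag_columns = dict(MAXQUANT_FLAGS if flag_columns is None else flag_columns)
    df = pd.read_csv(path, sep=_sep_for(path))
    id_col = next((c for c in ("Protein IDs", "protein_id", "Majority protein IDs")
                   if c in df.columns), None)
    if id_col is None:
        raise ParseError(f"{path}: no protein id column found")
    if df[id_col].duplicated().any():
        raise ParseError(f"{path}: duplicate protein ids")
    df = df.set_index(id_col)
    lfq_cols = {c: c[len(lfq_prefix):] for c in df.columns
                if c.startswith(lfq_prefix)}
    if not lfq_cols:
        raise ParseError(f"{path}: no '{lfq_prefix}<sample>' columns found")
    intensities = df[list(lfq_cols)].rename(columns=lfq_cols)
    missing = set(intensities.columns) - set(design)
    if missing:
        raise ParseError(
            f"{path}: samples missing from the design: {sorted(missing)}")
    flags = pd.DataFrame(index=df.index)
    for src, dst in flag_columns.items():
        if src in df.columns:
            flags[dst] = df[src].astype(str).str.strip() == "+"
        else:
            warnings.warn(f"{path}: flag column {src!r} absent, "
                          f"treated as all-false", stacklevel=2)
            flags[dst] = False
    groups = pd.Series(dict(design)).loc[list(intensities.columns)]
    return ProteinTable(intensities.astype(float), flags, groups)


def write_protein_groups(table: ProteinTable, path,
                         lfq_prefix: str = LFQ_PREFIX) -> None:
    """Write a ProteinTable back to the MaxQuant-style dialect (missing
    intensities as 0, flags as '+')."""
    out = table.intensities.rename(
        columns={c: lfq_prefix + c for c in table.intensities.columns})
    out = out.fillna(0.0)
    inv = {v: k for k, v in MAXQUANT_FLAGS.items()}
    for c in FLAG_COLUMNS:
        out[inv[c]] = np.where(table.flags[c], "+", "")
    out.to_csv(path, sep=_sep_for(path), index_label="Protein IDs",
               float_format=FLOAT_FORMAT)


def read_long_csv(path, required) -> pd.DataFrame:
    """Read a long-format assay table and check required columns."""
    df = pd.read_csv(path, sep=_sep_for(path), na_values=[NA_REP])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep=_sep_for(path), na_rep=NA_REP,
              float_format=FLOAT_FORMAT, index=index)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
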