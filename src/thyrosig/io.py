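"""Readers/writers for the tabular artifacts of the pipeline.

All formats are plain TSV (tab-separated, UTF-8, '.' decimal, no quoting);
probe and sample identifiers are opaque strings. Readers validate on entry:
duplicate identifiers, non-numeric cells, ragged rows and missing values are
rejected (never imputed), with the offending data row named where possible.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DataError, ParseError

GROUPS = ("ATC", "PTC", "NORMAL")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_are_table",
    "write_are_table",
    "read_mutation_table",
    "write_mutation_table",
    "read_qpcr_table",
    "write_qpcr_table",
    "read_ground_truth",
    "write_ground_truth",
    "gene_list_frame",
    "write_gene_list",
    "read_gene_list",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc


def _check_unique(ids: Iterable[str], kind: str, path) -> None:
    s = pd.Series(list(ids))
    dup = s[s.duplicated()]
    if len(dup):
        raise ParseError(
            f"{path}: duplicate {kind} id(s): {sorted(set(dup))}",
            row=int(dup.index[0]) + 1,
        )


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert a string frame to floats, naming the first bad cell's row."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() | ~np.isfinite(out)
    if bad.to_numpy().any():
        r = int(np.argwhere(bad.to_numpy())[0, 0])
        raise ParseError(
            f"{path}: non-numeric, missing or non-finite value for probe "
            f"'{df.index[r]}'",
            row=r + 1,
        )
    return out.astype(float)


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples log2 expression/ratio matrix.

    Expects a header row of sample ids; first column holds probe ids.
    Row and column order are preserved.
    """
    raw = _read_tsv(path, index_col=0)
    _check_unique(raw.index, "probe", path)
    _check_unique(raw.columns, "sample", path)
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: matrix has no sample columns")
    return _to_numeric(raw, path)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.Series:
    """Read a sample sheet: columns sample_id, group in {ATC, PTC, NORMAL}."""
    df = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample sheet must have a '{col}' column")
    _check_unique(df["sample_id"], "sample", path)
    bad = df.loc[~df["group"].isin(GROUPS)]
    if len(bad):
        raise ParseError(
            f"{path}: unknown group label(s): {sorted(set(bad['group']))}",
            row=int(bad.index[0]) + 1,
        )
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_sample_sheet(sheet: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": sheet.index, "group": sheet.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def check_sheet_covers(matrix: pd.DataFrame, sheet: pd.Series) -> None:
    """Every matrix sample must appear exactly once in the sheet."""
    missing = [s for s in matrix.columns if s not in sheet.index]
    if missing:
        raise DataError(f"samples missing from sample sheet: {missing}")


def read_annotation(path) -> pd.Series:
    """Read probe -> gene symbol mapping (many probes may share a gene)."""
    df = _read_tsv(path)
    for col in ("probe_id", "gene"):
        if col not in df.columns:
            raise ParseError(f"{path}: annotation must have a '{col}' column")
    _check_unique(df["probe_id"], "probe", path)
    empty = df.loc[df["gene"].str.strip() == ""]
    if len(empty):
        raise ParseError(
            f"{path}: empty gene symbol for probe '{empty['probe_id'].iloc[0]}'",
            row=int(empty.index[0]) + 1,
        )
    return pd.Series(df["gene"].to_numpy(), index=df["probe_id"], name="gene")


def write_annotation(annotation: pd.Series, path) -> None:
    pd.DataFrame(
        {"probe_id": annotation.index, "gene": annotation.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_are_table(path) -> pd.Series:
    """Read probe -> ARE flag (0/1) table."""
    df = _read_tsv(path)
    for col in ("probe_id", "are_flag"):
        if col not in df.columns:
            raise ParseError(f"{path}: ARE table must have a '{col}' column")
    _check_unique(df["probe_id"], "probe", path)
    bad = df.loc[~df["are_flag"].isin(["0", "1"])]
    if len(bad):
        raise ParseError(
            f"{path}: ARE flags must be 0 or 1", row=int(bad.index[0]) + 1
        )
    return pd.Series(
        df["are_flag"].astype(int).to_numpy(), index=df["probe_id"], name="are_flag"
    )


def write_are_table(are: pd.Series, path) -> None:
    pd.DataFrame(
        {"probe_id": are.index, "are_flag": are.astype(int).to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> pd.DataFrame:
    """Read mutation statuses: columns sample_id, gene, status (0/1)."""
    df = _read_tsv(path)
    for col in ("sample_id", "gene", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: mutation table must have a '{col}' column")
    _check_unique(
        df["sample_id"] + "\t" + df["gene"], "(sample, gene) pair", path
    )
    bad = df.loc[~df["status"].isin(["0", "1"])]
    if len(bad):
        raise ParseError(
            f"{path}: mutation status must be 0 or 1", row=int(bad.index[0]) + 1
        )
    out = df[["sample_id", "gene"]].copy()
    out["status"] = df["status"].astype(int)
    return out


def write_mutation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


QPCR_COLUMNS = ("gene", "sample", "ct_target", "ct_ref1", "ct_ref2")


def read_qpcr_table(path) -> pd.DataFrame:
    """Read qRT-PCR Ct values: gene, sample, ct_target, ct_ref1, ct_ref2.

    Replicate rows per (gene, sample) are allowed (technical triplicates).
    Ct values must be positive and finite.
    """
    df = _read_tsv(path)
    for col in QPCR_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: qPCR table must have a '{col}' column")
    out = df[list(QPCR_COLUMNS)].copy()
    for col in ("ct_target", "ct_ref1", "ct_ref2"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            raise ParseError(
                f"{path}: Ct values must be positive finite numbers ({col})",
                row=int(np.argwhere(bad.to_numpy())[0, 0]) + 1,
            )
        out[col] = vals.astype(float)
    return out


def write_qpcr_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path) -> None:
    """Write the per-probe ground-truth table (label + per-group mean effect)."""
    truth.table.to_csv(path, sep="\t", index_label="probe_id")


def read_ground_truth(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    for col in ("label", "atc_effect", "ptc_effect"):
        if col not in df.columns:
            raise ParseError(f"{path}: ground truth must have a '{col}' column")
    _check_unique(df.index, "probe", path)
    df["atc_effect"] = df["atc_effect"].astype(float)
    df["ptc_effect"] = df["ptc_effect"].astype(float)
    return df


def gene_list_frame(entries: pd.DataFrame, annotation: pd.Series | None) -> pd.DataFrame:
    """Normalize a probe list into the reportable gene-list layout.

    ``entries`` must have columns ``probe_id``, ``direction``,
    ``min_abs_log2_ratio``. Probes absent from the annotation get an empty
    gene field. Rows are sorted by direction ('up' before 'down', other
    patterns after, alphabetically), then by descending min |log2 ratio|.
    """
    df = entries.copy()
    if annotation is None:
        df["gene"] = ""
    else:
        df["gene"] = df["probe_id"].map(annotation).fillna("")
    rank = df["direction"].map({"up": 0, "down": 1}).fillna(2)
    df = (
        df.assign(_rank=rank)
        .sort_values(
            ["_rank", "direction", "min_abs_log2_ratio", "probe_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df[["probe_id", "gene", "direction", "min_abs_log2_ratio"]]


def write_gene_list(entries: pd.DataFrame, annotation: pd.Series | None, path) -> None:
    """Write a consensus/signature probe list as a sorted TSV report."""
    gene_list_frame(entries, annotation).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("probe_id", "gene", "direction", "min_abs_log2_ratio"):
        if col not in df.columns:
            raise ParseError(f"{path}: gene list must have a '{col}' column")
    df["min_abs_log2_ratio"] = df["min_abs_log2_ratio"].astype(float)
    return df
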