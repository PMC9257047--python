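"""Readers and writers for the pipeline's table formats.

All tables are TSV (UTF-8, '.' decimal — the dialect of TCGA-style
matrices); gene sets use the standard GMT exchange format.  No imputation
is performed anywhere: missing values are rejected at parse time for the
expression matrix and carried as explicit NA in the clinical table, with
listwise deletion applied (and counted) per analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix

__all__ = [
    "ParseError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_infiltration",
    "write_infiltration",
    "read_gene_list",
    "write_gene_list",
]


class ParseError(ValueError):
    """A file failed validation; the message names the offending location."""


def read_expression(path, annotation_path) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV plus sample annotation.

    The expression file has gene ids in the first column and sample ids in
    the header; the annotation TSV has columns ``sample_id`` and ``group``
    with values tumor/normal.  Duplicate gene ids, missing values and
    samples without an annotation are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids in {path}: {dup[:5]}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"missing value in {path} at gene {gene!r}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric cell in {path}: {exc}") from None

    ann = pd.read_csv(annotation_path, sep="\t")
    if not {"sample_id", "group"} <= set(ann.columns):
        raise ParseError(
            f"{annotation_path} must have columns sample_id and group"
        )
    groups = ann.set_index("sample_id")["group"]
    unknown = set(groups.index) - set(values.columns)
    if unknown:
        raise ParseError(
            f"annotation lists samples absent from the matrix: {sorted(unknown)[:5]}"
        )
    unlabeled = set(values.columns) - set(groups.index)
    if unlabeled:
        raise ParseError(f"samples without annotation: {sorted(unlabeled)[:5]}")
    bad = set(groups.unique()) - {"tumor", "normal"}
    if bad:
        raise ParseError(f"unknown group labels: {sorted(bad)}")
    return ExpressionMatrix(values=values, groups=groups.reindex(values.columns))


def write_expression(expr: ExpressionMatrix, path, annotation_path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    ann = expr.groups.rename("group").rename_axis("sample_id").reset_index()
    ann.to_csv(annotation_path, sep="\t", index=False)


_CLIN_COLS = ["sample_id", "os_time", "os_event", "stage", "t", "n", "m"]


def read_clinical(path) -> pd.DataFrame:
    """Read the per-sample clinical table.

    Columns: sample_id, os_time (> 0), os_event (0/1), stage, t, n, m
    (integer codes; explicit NA allowed for the staging columns).
    Returned with internal column names ``time``/``event``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_CLIN_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path} missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise ParseError(f"duplicate sample ids in {path}")
    times = pd.to_numeric(df["os_time"], errors="coerce")
    if times.isna().any():
        raise ParseError(f"non-numeric os_time in {path}")
    bad = times[times <= 0]
    if len(bad):
        raise ParseError(f"non-positive os_time for sample {bad.index[0]!r}")
    events = pd.to_numeric(df["os_event"], errors="coerce")
    if not events.isin([0, 1]).all():
        off = df.index[~events.isin([0, 1])][0]
        raise ParseError(f"os_event must be 0/1; offending sample {off!r}")
    out = pd.DataFrame(
        {
            "time": times.astype(float),
            "event": events.astype(int),
            "stage": pd.to_numeric(df["stage"], errors="coerce"),
            "t": pd.to_numeric(df["t"], errors="coerce"),
            "n": pd.to_numeric(df["n"], errors="coerce"),
            "m": pd.to_numeric(df["m"], errors="coerce"),
        },
        index=df.index,
    )
    return out


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.rename(columns={"time": "os_time", "event": "os_event"})
    out = out[["os_time", "os_event", "stage", "t", "n", "m"]]
    out.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs name, description, members")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if name in sets:
            raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
        if not members:
            raise ParseError(f"{path}:{ln}: set {name!r} has no members")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name, *members])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_infiltration(path) -> pd.DataFrame:
    """Cell-type x sample fraction table; fractions must be >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.astype(float)
    if (vals.to_numpy() < 0).any():
        raise ParseError(f"negative fraction in {path}")
    return vals


def write_infiltration(infil: pd.DataFrame, path) -> None:
    infil.rename_axis("cell_type").to_csv(path, sep="\t", float_format="%.8g")


def read_gene_list(path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def write_gene_list(genes: list[str], path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.extend(genes)
    Path(path).write_text("\n".join(lines) + "\n")
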