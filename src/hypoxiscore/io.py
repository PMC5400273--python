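"""Readers and writers for Ct tables, clinical tables and packaged fixtures.

Ct tables come in the two shapes a low-density-array export is commonly
massaged into:

* **wide** — first column ``gene``, one column per sample id;
* **long** — three columns ``gene,sample,ct``.

The layout is auto-detected from the header.  The tokens ``Undetermined``,
``NA`` and the empty string denote an undetermined well and become masked
cells.  Decimal separator is always the dot, independent of locale.

Writers emit Python shortest-repr floats, so a write/read round trip is
bit-identical for the documented dialect.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    CtMatrix,
    GenePanel,
    ValidationError,
)

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_clinical_table",
    "write_clinical_table",
    "load_gene_panel",
    "published_score_thresholds",
]

#: Tokens accepted as "no Ct value for this well".
MISSING_TOKENS = {"", "NA", "N/A", "Undetermined", "undetermined", "UNDETERMINED"}


class ParseError(ValueError):
    """Raised for a malformed cell, with row/column context."""


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_ct(token: str, row: str, col: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"unrecognized Ct token {token!r} at gene {row!r}, sample {col!r}"
        ) from None


def read_ct_table(path: str | Path, dialect: str | None = None) -> CtMatrix:
    """Read a wide or long Ct table from CSV/TSV.

    Parameters
    ----------
    path:
        File to read.  ``.tsv``/``.tab``/``.txt`` are tab-delimited,
        everything else comma-delimited.
    dialect:
        Force ``"wide"`` or ``"long"``; by default the layout is detected
        from the header (a ``gene,sample,ct`` header means long format).
    """
    path = Path(path)
    delim = _delimiter(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows or len(rows) < 2:
        raise ParseError(f"{path}: empty Ct table")
    header = [h.strip() for h in rows[0]]
    lowered = [h.lower() for h in header]
    if dialect is None:
        dialect = "long" if lowered[:3] == ["gene", "sample", "ct"] else "wide"
    if dialect == "long":
        return _read_long(rows[1:], path)
    if lowered[0] != "gene":
        raise ParseError(f"{path}: wide Ct table must start with a 'gene' column")
    return _read_wide(header[1:], rows[1:], path)


def _read_wide(samples: list[str], body: list[list[str]], path: Path) -> CtMatrix:
    dupes = sorted({s for s in samples if samples.count(s) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate sample ids in header: {dupes}")
    genes: list[str] = []
    data: list[list[float]] = []
    for row in body:
        if not row or not row[0].strip():
            continue
        gene = row[0].strip()
        genes.append(gene)
        cells = row[1:]
        if len(cells) != len(samples):
            raise ParseError(
                f"{path}: gene {gene!r} has {len(cells)} cells, expected {len(samples)}"
            )
        data.append([_parse_ct(c, gene, s) for c, s in zip(cells, samples)])
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate gene ids: {dupes}")
    frame = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
    return CtMatrix(frame)


def _read_long(body: list[list[str]], path: Path) -> CtMatrix:
    records: dict[tuple[str, str], float] = {}
    genes: list[str] = []
    samples: list[str] = []
    for row in body:
        if not row or not row[0].strip():
            continue
        if len(row) < 3:
            raise ParseError(f"{path}: long-format row too short: {row}")
        gene, sample = row[0].strip(), row[1].strip()
        key = (gene, sample)
        if key in records:
            raise ValidationError(
                f"{path}: duplicate (gene, sample) pair {key}"
            )
        records[key] = _parse_ct(row[2], gene, sample)
        if gene not in genes:
            genes.append(gene)
        if sample not in samples:
            samples.append(sample)
    frame = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
    for (g, s), v in records.items():
        frame.loc[g, s] = v
    return CtMatrix(frame)


def _fmt(value: float) -> str:
    return "Undetermined" if np.isnan(value) else repr(float(value))


def write_ct_table(ct: CtMatrix, path: str | Path, layout: str = "wide") -> None:
    """Write a Ct matrix as CSV/TSV in wide or long layout."""
    path = Path(path)
    delim = _delimiter(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if layout == "wide":
            writer.writerow(["gene", *ct.samples])
            for gene in ct.genes:
                row = ct.values.loc[gene]
                writer.writerow([gene, *(_fmt(v) for v in row.to_numpy())])
        elif layout == "long":
            writer.writerow(["gene", "sample", "ct"])
            for gene in ct.genes:
                for sample in ct.samples:
                    writer.writerow([gene, sample, _fmt(ct.values.at[gene, sample])])
        else:
            raise ValueError(f"unknown layout {layout!r}")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read and validate the canonical clinical CSV.

    Required columns are ``sample_id,age_group,er,pr,nodes,stage,grade_msbr,
    her2,relapse,rfs_months``; extra columns are kept but provoke a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).apply(lambda s: s.str.strip())
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra clinical columns {extra}", stacklevel=2)
    for col, caster in (
        ("stage", int),
        ("grade_msbr", int),
        ("relapse", int),
        ("rfs_months", float),
    ):
        try:
            df[col] = df[col].map(caster)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}: {exc}")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.reset_index(names="sample_id")
    df = df[list(CLINICAL_COLUMNS) + [c for c in df.columns if c not in CLINICAL_COLUMNS]]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(df.columns.tolist())
        for row in df.itertuples(index=False):
            out = []
            for col, v in zip(df.columns, row):
                out.append(repr(float(v)) if col == "rfs_months" else str(v))
            writer.writerow(out)


def load_gene_panel() -> GenePanel:
    """The packaged 47-assay panel: 45 hypoxia-related targets + RPL32 and 18S."""
    with resources.files("hypoxiscore.data").joinpath("gene_panel.csv").open() as fh:
        frame = pd.read_csv(fh)
    return GenePanel.from_frame(frame)


def published_score_thresholds() -> pd.Series:
    """The published per-gene optimum RQ thresholds of the 6-gene relapse signature."""
    with resources.files("hypoxiscore.data").joinpath(
        "published_thresholds.csv"
    ).open() as fh:
        frame = pd.read_csv(fh)
    return pd.Series(frame["threshold"].to_numpy(), index=frame["gene"], name="threshold")
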