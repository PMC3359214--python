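"""Readers and writers for the package's file dialects.

Formats handled: the genotype CSV dialect (marker header rows carrying
chromosome, cM and bp, then one row per line), expression TSV, BED/GFF3 gene
positions, two-column(+branch) GO annotation TSV, and the eQTL result table.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    ALT,
    COL,
    GENO_CODES,
    GENO_SYMBOLS,
    MISSING,
    EqtlRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    RileqtlError,
    RilGenotypes,
    records_to_frame,
)

log = logging.getLogger("rileqtl")

# ---------------------------------------------------------------------------
# genotype CSV dialect
#
#   row 1: id, marker ids...
#   row 2: (blank), chromosome per marker
#   row 3: (blank), cM position per marker
#   row 4: (blank), bp position per marker
#   rows 5+: line id, genotype symbols (A = Col, B = Alt, - = missing)
# ---------------------------------------------------------------------------


def read_cross(path: str | Path) -> tuple[GeneticMap, RilGenotypes]:
    """Read a genotype CSV file; returns the map and the call matrix."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 5:
        raise RileqtlError(f"{path}: genotype file needs >= 5 rows, got {len(rows)}")
    header, chrom_row, cm_row, bp_row = rows[:4]
    if header[0] != "id":
        raise RileqtlError(f"{path}:1: first header cell must be 'id'")
    marker_ids = header[1:]
    n = len(marker_ids)
    for i, row in enumerate(rows[1:4], start=2):
        if len(row) - 1 != n:
            raise RileqtlError(f"{path}:{i}: expected {n} marker fields, got {len(row) - 1}")
    markers = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom_row[1:]],
            "cm": [float(c) for c in cm_row[1:]],
            "bp": [int(float(c)) for c in bp_row[1:]],
        },
        index=pd.Index(marker_ids, name="marker"),
    )
    # physical length: last marker position per chromosome (refined by caller
    # if real lengths are known)
    lengths = markers.groupby("chrom", sort=False)["bp"].max().to_dict()
    gmap = GeneticMap(markers, lengths)

    line_ids: list[str] = []
    calls = np.empty((len(rows) - 4, n), dtype=np.int8)
    for j, row in enumerate(rows[4:], start=5):
        if len(row) - 1 != n:
            raise RileqtlError(f"{path}:{j}: expected {n} genotype fields, got {len(row) - 1}")
        line_ids.append(row[0])
        for k, sym in enumerate(row[1:]):
            try:
                calls[j - 5, k] = GENO_SYMBOLS[sym]
            except KeyError:
                raise RileqtlError(f"{path}:{j}: unknown genotype symbol {sym!r}") from None
    return gmap, RilGenotypes(line_ids, calls, gmap)


def write_cross(gmap: GeneticMap, genos: RilGenotypes, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *gmap.markers.index])
        w.writerow(["", *gmap.markers["chrom"]])
        w.writerow(["", *(f"{c:g}" for c in gmap.markers["cm"])])
        w.writerow(["", *(str(int(b)) for b in gmap.markers["bp"])])
        for line_id, row in zip(genos.line_ids, genos.calls):
            w.writerow([line_id, *(GENO_CODES[int(c)] for c in row)])


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a traits x lines TSV (first column trait id, header = line ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise RileqtlError(f"{path}: duplicate trait id {dup!r}")
    # empty cells arrive as NaN via read_csv; anything non-numeric is a
    # dialect violation and raises
    values = df.apply(pd.to_numeric)
    return ExpressionMatrix(values.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="trait", float_format="%.6g")


# ---------------------------------------------------------------------------
# gene positions (BED 0-based half-open / GFF3 1-based closed)
# ---------------------------------------------------------------------------


def read_gene_positions(path: str | Path, fmt: str = "BED") -> GeneAnnotation:
    """Read gene physical positions; representative position = feature midpoint (1-based)."""
    path = Path(path)
    fmt = fmt.upper()
    rows: list[tuple[str, str, int, str]] = []
    if fmt == "BED":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise RileqtlError(f"{path}:{i}: BED line needs >= 4 fields")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                if end <= start:
                    raise RileqtlError(f"{path}:{i}: zero-length or inverted BED feature")
                strand = parts[5] if len(parts) > 5 else "."
                # 0-based half-open [start, end) -> 1-based closed [start+1, end]
                mid = (start + 1 + end) // 2
                rows.append((name, chrom, mid, strand))
    elif fmt == "GFF3":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise RileqtlError(f"{path}:{i}: GFF3 line needs 9 fields")
                chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
                if end < start:
                    raise RileqtlError(f"{path}:{i}: inverted GFF3 feature")
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("ID") or attrs.get("Name")
                if name is None:
                    raise RileqtlError(f"{path}:{i}: feature without ID attribute")
                mid = (start + end) // 2
                rows.append((name, chrom, mid, strand))
    else:
        raise RileqtlError(f"unknown gene-position format {fmt!r}")
    df = pd.DataFrame(rows, columns=["trait", "chrom", "bp", "strand"]).set_index("trait")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise RileqtlError(f"{path}: trait {dup!r} annotated twice")
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# GO annotation TSV: gene_id TAB term_id [TAB branch]; pre-propagated
# ---------------------------------------------------------------------------


def read_go_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df["branch"] = "biological_process"
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
    else:
        raise RileqtlError(f"{path}: GO TSV needs >= 2 columns")
    df.columns = ["gene", "term", "branch"]
    return df


# ---------------------------------------------------------------------------
# eQTL result table
# ---------------------------------------------------------------------------

_CLASS_TOKEN = {"local": "cis", "distant": "trans", "unclassified": "NA"}
_TOKEN_CLASS = {v: k for k, v in _CLASS_TOKEN.items()}

_EQTL_COLUMNS = [
    "trait", "eQTL_chr", "type", "peak.bp", "inf.pb", "sup.pb",
    "LOD", "Add", "Rsq", "p", "q", "peak.cm", "inf.cm", "sup.cm",
]


def write_eqtl_table(records: Iterable[EqtlRecord], path: str | Path) -> None:
    """Write the eQTL table; local/distant are printed as 'cis'/'trans' tokens."""
    df = records_to_frame(records)
    out = pd.DataFrame(
        {
            "trait": df["trait"],
            "eQTL_chr": df["chrom"],
            "type": df["classification"].map(_CLASS_TOKEN),
            "peak.bp": df["peak_bp"],
            "inf.pb": df["inf_bp"],
            "sup.pb": df["sup_bp"],
            "LOD": df["lod"],
            "Add": df["add"],
            "Rsq": df["rsq"],
            "p": df["p"],
            "q": df["q"],
            "peak.cm": df["peak_cm"],
            "inf.cm": df["inf_cm"],
            "sup.cm": df["sup_cm"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_eqtl_table(path: str | Path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"eQTL_chr": str, "trait": str})
    missing = set(_EQTL_COLUMNS[:11]) - set(df.columns)
    if missing:
        raise RileqtlError(f"{path}: eQTL table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            EqtlRecord(
                trait=row["trait"],
                chrom=row["eQTL_chr"],
                peak_cm=float(row.get("peak.cm", np.nan)),
                peak_bp=int(row["peak.bp"]),
                inf_bp=int(row["inf.pb"]),
                sup_bp=int(row["sup.pb"]),
                inf_cm=float(row.get("inf.cm", np.nan)),
                sup_cm=float(row.get("sup.cm", np.nan)),
                lod=float(row["LOD"]),
                add=float(row["Add"]),
                rsq=float(row["Rsq"]),
                classification=_TOKEN_CLASS.get(str(row["type"]), "unclassified"),
                p=float(row["p"]),
                q=float(row["q"]),
            )
        )
    return records
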