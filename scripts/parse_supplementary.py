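#!/usr/bin/env python
"""Convenience parser for study supplementary taxon tables.

Counts the taxa listed in a supplementary workbook sheet (.xlsx, via
openpyxl) or a plain TSV export with a taxon-id column. This is not part of
the core pipeline — the analysis consumes probe-call TSVs — but lets a user
who has downloaded a supplementary taxon list check its size and extract the
taxon ids.

Usage:  python scripts/parse_supplementary.py TABLE [--column OTU_ID]
"""

from __future__ import annotations

import argparse
from pathlib import Path


def taxon_ids_from_table(path: str | Path, column: str = "OTU_ID") -> list[str]:
    """Return the non-empty values of the taxon-id column, header excluded."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        import openpyxl

        ws = openpyxl.load_workbook(path, read_only=True).worksheets[0]
        rows = ws.iter_rows(values_only=True)
        header = [str(c) if c is not None else "" for c in next(rows)]
        if column not in header:
            raise ValueError(f"{path}: no column {column!r} in {header}")
        j = header.index(column)
        return [str(r[j]) for r in rows if r[j] is not None and str(r[j]).strip()]
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if column not in (reader.fieldnames or []):
            raise ValueError(f"{path}: no column {column!r} in {reader.fieldnames}")
        return [row[column] for row in reader if row[column] and row[column].strip()]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table", type=Path)
    ap.add_argument("--column", default="OTU_ID")
    args = ap.parse_args()
    ids = taxon_ids_from_table(args.table, args.column)
    print(f"{len(ids)} taxa in {args.table}")


if __name__ == "__main__":
    main()
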