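"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and eQTL flag tables are tab-separated with a header row
of sample/tissue ids and gene ids in the first column; metadata is
tab-separated with sample ids in the first column; gene sets use the
standard GMT format (name, description, then tab-separated gene ids, one
set per line).  All readers validate ids and cell types and name the
offending line or column in their error messages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from chronosom.annotate import GeneSetCollection


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix; ids must be unique, cells numeric."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicated gene ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicated sample ids {dup}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path.name}: non-numeric cells in columns {non_numeric}")
    return df.astype(float)


def write_matrix(X: pd.DataFrame, path: str | Path) -> None:
    X.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicated sample ids {dup}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path.name}:{lineno}: ragged GMT line "
                "(need name, description and at least one gene)"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path.name}:{lineno}: duplicated set name {name!r}")
        if not genes:
            raise ValueError(f"{path.name}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue 0/1 flag table (TSV)."""
    table = read_matrix(path)
    values = table.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{Path(path).name}: eQTL flags must be 0/1")
    return table.astype(int)


def write_eqtl_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
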