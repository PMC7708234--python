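"""Readers and writers for counts, designs, gene sets and result tables.

All text outputs are UTF-8 with Unix line endings; floats are written in
scientific notation with 12 significant digits so that written tables diff
reproducibly and round-trip to 12 significant digits.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .datamodel import (
    ENRICHMENT_COLUMNS,
    GENE_FIT_COLUMNS,
    CountMatrix,
    GeneSetCollection,
    StudyDesign,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]

FLOAT_FORMAT = "%.11e"  # 12 significant digits


def _float_fmt(x) -> str:
    if pd.isna(x):
        return "NA"
    return FLOAT_FORMAT % x


def read_counts(path: str | os.PathLike, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: first column gene id, header row of sample ids, tab-separated.
    ``mtx``: MatrixMarket coordinate file with sibling ``<stem>.genes.txt``
    and ``<stem>.samples.txt`` id files (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric entries in count matrix {path}")
        if values.size and np.any(values != np.floor(values)):
            raise ValueError(f"non-integer counts in {path}")
        return CountMatrix(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=values.astype(np.int64) if values.size else values.reshape(df.shape),
        )
    if format == "mtx":
        mat = mmread(path)
        mat = mat.toarray() if hasattr(mat, "toarray") else np.asarray(mat)
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        return CountMatrix(gene_ids=genes, sample_ids=samples, counts=np.asarray(mat))
    raise ValueError(f"unknown count format {format!r}; expected 'tsv' or 'mtx'")


def write_counts(cm: CountMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = cm.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n")
        return
    if format == "mtx":
        mmwrite(path, coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
        return
    raise ValueError(f"unknown count format {format!r}")


def read_design(path: str | os.PathLike) -> StudyDesign:
    """Read a per-sample design TSV (validates columns and factor levels)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | os.PathLike) -> None:
    df = design.table.copy()
    for col in ("tissue_mg", "library_size"):
        df[col] = df[col].map(_float_fmt)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read gene sets in GMT format: ``set_id<TAB>description<TAB>member...``.

    Duplicate members within a line are deduplicated (set semantics); a line
    with fewer than three fields is a format error reported with its line
    number.
    """
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected id, description and at least one member"
                )
            sid, desc, *members = fields
            sets[sid] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sid, (desc, members) in collection:
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike, schema: str | None = None) -> None:
    """Write a result table as TSV.

    ``schema`` may be ``"gene_fit"`` or ``"enrichment"`` to enforce the
    supplementary-file column order.
    """
    df = df.copy()
    if schema == "gene_fit":
        cols = [c for c in GENE_FIT_COLUMNS if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols]
    elif schema == "enrichment":
        cols = [c for c in ENRICHMENT_COLUMNS if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols]
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(_float_fmt)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
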