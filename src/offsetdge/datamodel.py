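"""Core data containers for count matrices, study designs, gene sets and
result tables.

The containers are thin, validated wrappers around numpy arrays and pandas
DataFrames.  Gene and sample identifiers are opaque strings; no identifier
mapping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "GENE_FIT_COLUMNS",
    "ENRICHMENT_COLUMNS",
    "LEG_LEVELS",
    "SETS_LEVELS",
    "TIME_LEVELS",
    "RESTED_TIMES",
    "ACUTE_TIMES",
]

LEG_LEVELS = ("left", "right")
SETS_LEVELS = ("single", "multiple")  # "single" is the reference level
TIME_LEVELS = ("w0", "w2pre", "w2post", "w12")
RESTED_TIMES = ("w0", "w2pre", "w12")  # reference w0
ACUTE_TIMES = ("w2pre", "w2post")  # reference w2pre

#: Column order of a per-gene fit table.  The leading columns mirror the
#: supplementary gene-estimate schema; columns after ``pvalue_adjust`` are
#: artifact extensions (suffix-free names kept distinct from the core set).
GENE_FIT_COLUMNS = [
    "ensemblid",
    "normalization_model",
    "interaction_model",
    "coefficient",
    "estimate",
    "se",
    "zvalue",
    "pvalue",
    "pvalue_adjust",
    "log2fc",
    "msd",
    "convergence",
    "de",
]

#: Column order of an enrichment result table (supplementary annotation schema).
ENRICHMENT_COLUMNS = [
    "ID",
    "go_category",
    "name",
    "normalization_model",
    "coefficient",
    "cerno_statistic",
    "cerno_auc",
    "cerno_pval",
    "cerno_padj",
    "gsea_es",
    "gsea_nes",
    "gsea_pval",
    "gsea_padj",
    "ora_geneRatio",
    "ora_pval",
    "ora_padj",
    "set_size",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers (e.g. Ensembl gene ids), unique.
    sample_ids : list of str
        Column identifiers, unique.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts."""
        return self.counts.sum(axis=0)

    def cpm(self, pseudo: float = 0.0) -> np.ndarray:
        """Counts per million, optionally with a pseudo-CPM added."""
        n = self.library_sizes().astype(float)
        return self.counts / n[None, :] * 1e6 + pseudo

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), self.sample_ids, self.counts[rows])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(self.gene_ids, list(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class StudyDesign:
    """Per-sample metadata for the within-participant training design.

    One row per sample with participant, leg, volume condition (``sets``),
    time point, tissue used in cDNA synthesis (mg) and total mapped reads.
    """

    table: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "participant_id",
        "leg",
        "sets",
        "time",
        "tissue_mg",
        "library_size",
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"design is missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["participant_id"] = df["participant_id"].astype(str)
        _check_unique(df["sample_id"], "sample")
        for col, levels in (("leg", LEG_LEVELS), ("sets", SETS_LEVELS), ("time", TIME_LEVELS)):
            bad = set(df[col]) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} level(s): {sorted(bad)}; allowed {levels}")
        df["tissue_mg"] = df["tissue_mg"].astype(float)
        df["library_size"] = df["library_size"].astype(float)
        if not ((df["tissue_mg"] > 0) & np.isfinite(df["tissue_mg"])).all():
            raise ValueError("tissue_mg must be finite and > 0 for all samples")
        if not ((df["library_size"] > 0) & np.isfinite(df["library_size"])).all():
            raise ValueError("library_size must be finite and > 0 for all samples")
        dup = df.duplicated(subset=["participant_id", "leg", "time"])
        if dup.any():
            rows = df.loc[dup, ["participant_id", "leg", "time"]].iloc[0].tolist()
            raise ValueError(f"duplicated (participant, leg, time): {rows}")
        # volume condition is a property of a leg, fixed for the whole study
        nuniq = df.groupby(["participant_id", "leg"])["sets"].nunique()
        if (nuniq > 1).any():
            raise ValueError("sets must be constant within (participant, leg)")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "StudyDesign":
        return StudyDesign(self.table.loc[mask].reset_index(drop=True))

    def restrict_times(self, times) -> "StudyDesign":
        return self.subset(self.table["time"].isin(times))

    def aligned_to(self, sample_ids) -> "StudyDesign":
        """Reorder rows to match ``sample_ids`` (e.g. a CountMatrix column order)."""
        df = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise KeyError(f"samples not in design: {missing[:5]}")
        out = df.loc[list(sample_ids)].reset_index()
        return StudyDesign(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDesign):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional scoring universe.

    ``sets`` maps set id -> (description, frozenset of member gene ids).
    Intersection with a universe happens at enrichment time; the collection
    stores members verbatim.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset]] = {}
        for sid, (desc, members) in self.sets.items():
            clean[str(sid)] = (str(desc), frozenset(members))
        self.sets = clean
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty sets are dropped."""
        uni = frozenset(universe)
        sets = {}
        for sid, (desc, members) in self.sets.items():
            inter = members & uni
            if inter:
                sets[sid] = (desc, inter)
        return GeneSetCollection(sets=sets, universe=uni)
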