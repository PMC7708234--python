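"""Gene-set enrichment: MSD-ranked CERNO, preranked GSEA and hypergeometric
over-representation analysis.

The minimum significant difference (MSD) is a direction-free confidence
metric: the lower CI bound of a positive log fold-change, or the negated
upper bound of a negative one, so MSD > 0 exactly when the CI excludes
zero.  The CERNO statistic aggregates the ranks of a set's genes,
F = -2 * sum ln(R_g / N), chi-squared with 2*|set| df under a uniform null,
with a Mann-Whitney AUC as its effect size.  GSEA follows the weighted
running-sum formulation (exponent 1) on a log2 fold-change ranking with a
gene-label permutation null and sign-stratified NES.  ORA is the exact
upper-tail hypergeometric test of a DE list against each set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedGeneList",
    "msd",
    "cerno",
    "gsea",
    "ora",
    "enrich_all",
]


@dataclass
class RankedGeneList:
    """Genes ordered by a metric (descending), with average ranks for ties."""

    gene_ids: list[str]
    metric: np.ndarray  # aligned to gene_ids, descending
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != self.metric.size:
            raise ValueError("gene_ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranking")
        order = np.argsort(-self.metric, kind="stable")
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.metric = self.metric[order]
        # average ranks for tied metric values, 1..N
        r = pd.Series(-self.metric).rank(method="average").to_numpy()
        self._ranks = {g: r[i] for i, g in enumerate(self.gene_ids)}

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def ranks(self, genes) -> np.ndarray:
        return np.array([self._ranks[g] for g in genes])

    @classmethod
    def from_values(cls, values: dict[str, float], metric_name: str = "metric"):
        genes = list(values)
        return cls(genes, np.array([values[g] for g in genes]), metric_name)


def msd(estimate: float, se: float, level: float = 0.95) -> float:
    """Minimum significant difference of a fold-change estimate.

    ``estimate - z*se`` for positive estimates, ``-(estimate + z*se)`` for
    negative ones (and ``-z*se`` at exactly zero), with z the two-sided
    normal quantile at ``level``.  Positive exactly when the level-CI
    excludes zero; symmetric in the sign of the estimate.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if estimate > 0:
        return estimate - z * se
    if estimate < 0:
        return -(estimate + z * se)
    return -z * se


def cerno(ranked: RankedGeneList, members) -> dict:
    """Rank aggregation test of one gene set against a ranking.

    Returns the statistic ``F = -2 sum ln(R/N)``, its chi-squared degrees of
    freedom ``2*n1``, the upper-tail p-value, and the Mann-Whitney AUC of
    set genes against the rest.
    """
    genes = [g for g in members if g in ranked._ranks]
    n1 = len(genes)
    if n1 == 0:
        raise ValueError("gene set has empty intersection with the ranking universe")
    N = ranked.n
    r = ranked.ranks(genes)
    F = float(-2.0 * np.sum(np.log(r / N)))
    df = 2 * n1
    p = float(stats.chi2.sf(F, df))
    n2 = N - n1
    if n2 == 0:
        auc = 0.5
    else:
        auc = float((n1 * n2 + n1 * (n1 + 1) / 2.0 - np.sum(r)) / (n1 * n2))
    return {"statistic": F, "df": df, "pvalue": p, "auc": auc, "n1": n1}


def _es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the weighted running sum (exponent 1)."""
    hits = np.abs(metric) * in_set
    total_hit = hits.sum()
    n_miss = in_set.size - int(in_set.sum())
    if total_hit == 0:
        raise ValueError("all gene-level metric values in the set are zero")
    if n_miss == 0:
        return 1.0
    inc = np.where(in_set, hits / total_hit, -1.0 / n_miss)
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea(
    ranked: RankedGeneList,
    members,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Preranked GSEA of one gene set.

    The enrichment score is the signed extremum of the running sum that
    increments by ``|s_g| / sum_set |s|`` at set genes and decrements by
    ``1/(N - n1)`` elsewhere.  The null is formed by drawing random gene
    labels of the same size (gene permutation); NES divides ES by the mean
    |ES*| of same-sign permutations and p is the one-sided permutation tail
    with the +1 correction.
    """
    in_set = np.array([g in set(members) for g in ranked.gene_ids])
    n1 = int(in_set.sum())
    if n1 == 0:
        raise ValueError("gene set has empty intersection with the ranking universe")
    metric = ranked.metric
    if np.all(metric == 0):
        raise ValueError("all gene-level metric values are zero")
    es = _es(metric, in_set)
    rng = np.random.default_rng(seed)
    N = ranked.n
    es_null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(N, size=n1, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        es_null[b] = _es(metric, mask)
    same = es_null * np.sign(es) > 0
    n_same = int(same.sum())
    if n_same == 0:
        return {"es": es, "nes": np.nan, "pvalue": 1.0, "n_perm": n_perm, "flagged": True}
    mean_abs = np.mean(np.abs(es_null[same]))
    nes = es / mean_abs if mean_abs > 0 else np.nan
    exceed = int(np.sum(np.abs(es_null[same]) >= abs(es)))
    p = (1.0 + exceed) / (1.0 + n_same)
    return {"es": es, "nes": float(nes), "pvalue": float(p), "n_perm": n_perm, "flagged": False}


def ora(de_genes, universe, members) -> dict:
    """Upper-tail hypergeometric over-representation test.

    Drawing ``|de|`` genes from a universe containing ``|set|`` members,
    the p-value is ``P(X >= k)`` for the observed overlap ``k``.
    """
    uni = set(universe)
    de = set(de_genes)
    if not de <= uni:
        raise ValueError("DE genes must be a subset of the universe")
    mem = set(members) & uni
    k = len(de & mem)
    n_de = len(de)
    if n_de == 0:
        return {"overlap": 0, "gene_ratio": np.nan, "pvalue": 1.0, "flagged": True}
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(mem), n_de))
    return {"overlap": k, "gene_ratio": k / n_de, "pvalue": p, "flagged": False}


def _bh(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def enrich_all(
    table: pd.DataFrame,
    sets,
    coefficient: str,
    n_perm: int = 10000,
    seed: int = 0,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run MSD/CERNO, GSEA and ORA for every set against one fit table
    coefficient; BH-adjust each test family across sets.

    ``table`` is a per-gene fit table (one normalization model); converged
    rows for ``coefficient`` define the universe.  The CERNO ranking is MSD
    descending, the GSEA metric log2 fold-change, and the ORA DE list the
    rows flagged by :func:`offsetdge.glmm.call_de` (recomputed here from
    ``lfc_threshold``/``alpha`` if the table carries no DE flags).
    """
    models = table["normalization_model"].unique()
    frames = []
    for model in models:
        sub = table[
            (table["normalization_model"] == model)
            & (table["coefficient"] == coefficient)
            & table["convergence"].isin(["converged", "boundary"])
            & table["msd"].notna()
        ]
        if sub.empty:
            continue
        universe = sub["ensemblid"].tolist()
        ranked_msd = RankedGeneList(universe, sub["msd"].to_numpy(), "msd")
        ranked_fc = RankedGeneList(universe, sub["log2fc"].to_numpy(), "log2fc")
        if "de" in sub.columns and sub["pvalue_adjust"].notna().any():
            de_genes = sub.loc[sub["de"].astype(bool), "ensemblid"].tolist()
        else:
            adj = _bh(sub["pvalue"].to_numpy())
            de_mask = (sub["log2fc"].abs().to_numpy() > lfc_threshold) & (adj < alpha)
            de_genes = sub.loc[de_mask, "ensemblid"].tolist()
        restricted = sets.restricted_to(universe)
        rng_seeds = np.random.SeedSequence(seed).generate_state(max(len(restricted), 1), dtype=np.uint32)
        rows = []
        for si, (sid, (desc, members)) in enumerate(restricted):
            c = cerno(ranked_msd, members)
            try:
                g = gsea(ranked_fc, members, n_perm=n_perm, seed=int(rng_seeds[si]))
            except ValueError:
                g = {"es": np.nan, "nes": np.nan, "pvalue": np.nan}
            o = ora(de_genes, universe, members)
            go_category, name = _split_description(desc)
            rows.append(
                {
                    "ID": sid,
                    "go_category": go_category,
                    "name": name,
                    "normalization_model": model,
                    "coefficient": coefficient,
                    "cerno_statistic": c["statistic"],
                    "cerno_auc": c["auc"],
                    "cerno_pval": c["pvalue"],
                    "gsea_es": g["es"],
                    "gsea_nes": g["nes"],
                    "gsea_pval": g["pvalue"],
                    "ora_geneRatio": o["gene_ratio"],
                    "ora_pval": o["pvalue"],
                    "set_size": len(members),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["cerno_padj"] = _bh(df["cerno_pval"].to_numpy())
        gs = df["gsea_pval"].notna()
        df["gsea_padj"] = np.nan
        if gs.any():
            df.loc[gs, "gsea_padj"] = _bh(df.loc[gs, "gsea_pval"].to_numpy())
        df["ora_padj"] = _bh(df["ora_pval"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "ID", "go_category", "name", "normalization_model", "coefficient",
                "cerno_statistic", "cerno_auc", "cerno_pval", "cerno_padj",
                "gsea_es", "gsea_nes", "gsea_pval", "gsea_padj",
                "ora_geneRatio", "ora_pval", "ora_padj", "set_size",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _split_description(desc: str) -> tuple[str, str]:
    """GMT descriptions of the form ``bp|Collagen fibril organization`` carry
    a GO-category prefix; anything else maps to an empty category."""
    if "|" in desc:
        cat, name = desc.split("|", 1)
        if cat in ("bp", "cc", "mf"):
            return cat, name
    return "", desc
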