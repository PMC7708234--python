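"""Quantifier-agnostic quality metrics: myosin heavy chain family profiles
against protein fiber types, and paired-replicate technical variation.

Expressing the members of a gene family (MYH7, MYH2, MYH1 in muscle) as
fractions of the family total removes any need for between-sample
normalization; the fractions can be correlated directly with
immunohistochemistry fiber-type fractions (Type I, IIA, IIX).  Technical
variation is measured as log2 differences of stably expressed genes between
the two baseline biopsies of each participant (one per leg), which carry
minimal biological difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, StudyDesign

__all__ = [
    "FamilyProfile",
    "family_fractions",
    "profile_correlation",
    "paired_log_differences",
    "split_hybrid_fibers",
]

#: mRNA family member -> corresponding fiber-type protein
MYH_FIBER_MAP = {"MYH7": "type_I", "MYH2": "type_IIA", "MYH1": "type_IIX"}


@dataclass
class FamilyProfile:
    """Per-sample fractions over an ordered gene family (rows sum to 1)."""

    members: list[str]
    sample_ids: list[str]
    fractions: np.ndarray  # (n_samples, n_members)
    excluded: list[str]  # samples with zero family total

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size:
            if np.any(fr < 0):
                raise ValueError("fractions must be non-negative")
            if not np.allclose(fr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("fractions must sum to 1 per sample")
        self.fractions = fr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.members)


def family_fractions(counts: CountMatrix, family: list[str]) -> FamilyProfile:
    """Per-sample fractions of each family member over the family total.

    Samples whose family total is zero are flagged and excluded (their
    fractions are undefined).
    """
    sub = counts.subset_genes(family)
    totals = sub.counts.sum(axis=0).astype(float)
    keep = totals > 0
    excluded = [s for s, k in zip(counts.sample_ids, keep) if not k]
    fr = (sub.counts[:, keep] / totals[keep]).T
    kept_ids = [s for s, k in zip(counts.sample_ids, keep) if k]
    return FamilyProfile(members=list(family), sample_ids=kept_ids, fractions=fr, excluded=excluded)


def profile_correlation(
    mrna: FamilyProfile,
    protein: FamilyProfile,
    pairing: dict[str, str] | None = None,
    member_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between mRNA and protein family fractions.

    ``pairing`` maps mRNA sample ids to protein specimen ids (identity by
    default); ``member_map`` maps mRNA members to protein members (e.g.
    MYH7 -> type_I), defaulting to positional order.  Returns one row per
    member plus a pooled row over all members; members with zero variance
    in either vector get ``r = NaN`` and a flag.
    """
    if pairing is None:
        pairing = {s: s for s in mrna.sample_ids}
    if member_map is None:
        member_map = dict(zip(mrna.members, protein.members))
    m_frame = mrna.to_frame()
    p_frame = protein.to_frame()
    shared = [s for s in mrna.sample_ids if s in pairing and pairing[s] in p_frame.index]
    rows = []
    pooled_x: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    for member in mrna.members:
        pm = member_map[member]
        x = m_frame.loc[shared, member].to_numpy()
        y = p_frame.loc[[pairing[s] for s in shared], pm].to_numpy()
        if len(x) < 3:
            raise ValueError("need at least 3 paired observations per member")
        flagged = x.std() == 0 or y.std() == 0
        r = np.nan if flagged else float(np.corrcoef(x, y)[0, 1])
        rows.append({"member": member, "protein": pm, "n": len(x), "r": r, "flagged": flagged})
        pooled_x.append(x)
        pooled_y.append(y)
    X = np.concatenate(pooled_x)
    Y = np.concatenate(pooled_y)
    pooled_flag = X.std() == 0 or Y.std() == 0
    rows.append(
        {
            "member": "pooled",
            "protein": "pooled",
            "n": len(X),
            "r": np.nan if pooled_flag else float(np.corrcoef(X, Y)[0, 1]),
            "flagged": pooled_flag,
        }
    )
    return pd.DataFrame(rows)


def paired_log_differences(
    counts: CountMatrix,
    design: StudyDesign,
    gene_subset: list[str],
    time: str = "w0",
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """Log2 differences of stably expressed genes between paired baseline
    biopsies (left vs right leg of each participant).

    Counts are converted to CPM per sample; the difference is
    ``log2((CPM_left + c) / (CPM_right + c))`` with pseudo-CPM ``c``
    guarding zeros.  Participants missing either leg at ``time`` are
    skipped.  Returns the full per-gene, per-participant distribution; the
    mean absolute difference is the headline technical-variation summary.
    """
    design = design.aligned_to(counts.sample_ids)
    base = design.table[design.table["time"] == time]
    # CPM uses the full library sizes, then restricts to the gene subset
    cpm = pd.DataFrame(
        counts.cpm(), index=counts.gene_ids, columns=counts.sample_ids
    ).loc[list(gene_subset)]
    rows = []
    for pid, grp in base.groupby("participant_id"):
        legs = dict(zip(grp["leg"], grp["sample_id"]))
        if "left" not in legs or "right" not in legs:
            continue
        d = np.log2(cpm[legs["left"]] + pseudo_cpm) - np.log2(cpm[legs["right"]] + pseudo_cpm)
        for gene, val in d.items():
            rows.append({"participant_id": pid, "gene_id": gene, "log2_difference": float(val)})
    return pd.DataFrame(rows)


def split_hybrid_fibers(
    protein: pd.DataFrame,
    hybrid_col: str = "type_IIA_IIX",
    targets: tuple[str, str] = ("type_IIA", "type_IIX"),
) -> pd.DataFrame:
    """Split hybrid-fiber fractions 0.5/0.5 into their two pure types."""
    out = protein.copy()
    if hybrid_col in out.columns:
        half = out[hybrid_col] / 2.0
        for t in targets:
            out[t] = out.get(t, 0.0) + half
        out = out.drop(columns=[hybrid_col])
    return out
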