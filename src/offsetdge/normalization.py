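"""RNA-composition (TMM) factors, effective library sizes and tissue offsets.

The effective library size of a sample is its total count multiplied by a
trimmed-mean-of-M-values composition factor; the model covariate is that
value divided by the cohort median ("scaled" effective library size).  The
tissue offset is the natural log of the milligrams of tissue whose RNA went
into the library, turning modelled rates into per-unit-tissue expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, StudyDesign

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "effective_library_sizes",
    "tissue_offsets",
]


@dataclass
class NormalizationFactors:
    """Per-sample normalization quantities, aligned to ``sample_ids``."""

    sample_ids: list[str]
    tmm_factor: np.ndarray  # geometric-mean-centred, dimensionless
    effective_library_size: np.ndarray  # reads x factor
    scaled_effective_library_size: np.ndarray  # median-normalised
    tissue_offset: np.ndarray | None = None  # ln(tissue_mg)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "tmm_factor": self.tmm_factor,
                "effective_library_size": self.effective_library_size,
                "scaled_effective_library_size": self.scaled_effective_library_size,
            }
        )
        if self.tissue_offset is not None:
            df["tissue_offset"] = self.tissue_offset
        return df


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean fraction
    frac = np.quantile(counts / lib_sizes[None, :], 0.75, axis=0)
    return int(np.argmin(np.abs(frac - frac.mean())))


def _tmm_pair(
    yk: np.ndarray,
    yr: np.ndarray,
    nk: float,
    nr: float,
    logratio_trim: float,
    abs_trim: float,
    min_shared: int,
) -> tuple[float, bool]:
    """TMM factor of sample k against reference r (before centring).

    Returns ``(factor, flagged)`` where ``flagged`` marks a degenerate pair
    with fewer than ``min_shared`` genes positive in both samples.
    """
    pos = (yk > 0) & (yr > 0)
    if pos.sum() < min_shared:
        return 1.0, True
    yk = yk[pos].astype(float)
    yr = yr[pos].astype(float)
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    # precision weights: delta-method variance of M under binomial sampling
    w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
    if np.max(np.abs(m)) < 1e-6:
        # perfectly proportional pair
        return 1.0, False
    # published trimmed-mean defaults: trim logratio_trim of the M values and
    # abs_trim of the A values from EACH tail
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks 1..n; ties get average ranks so symmetric tails trim symmetrically
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0, True
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0, True
    return float(2.0 ** f), False


def tmm_factors(
    counts: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    min_shared: int = 10,
) -> np.ndarray:
    """Trimmed-mean-of-M-values composition factors, geometric-mean centred.

    For each sample k against a reference r, over genes positive in both:
    ``M = log2((y_k/N_k)/(y_r/N_r))`` and ``A = 0.5*log2((y_k/N_k)*(y_r/N_r))``.
    The most extreme 30% of M values and 5% of A values are discarded from
    each tail (the published defaults of the trimmed-mean method); the
    factor is ``2**(sum(w*M)/sum(w))`` with inverse-variance precision
    weights.  The reference defaults to the sample whose
    upper-quartile count fraction is closest to the cohort mean of those
    fractions.  Factors are divided by their geometric mean so they multiply
    to one.
    """
    y = counts.counts
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    n = y.sum(axis=0).astype(float)
    if np.any(n <= 0):
        raise ValueError("every sample must have a positive total count")
    if ref_sample is None:
        ref = _choose_reference(y, n)
    else:
        ref = counts.sample_ids.index(ref_sample)
    factors = np.ones(counts.n_samples)
    for k in range(counts.n_samples):
        if k == ref:
            continue
        f, flagged = _tmm_pair(y[:, k], y[:, ref], n[k], n[ref], logratio_trim, abs_trim, min_shared)
        if flagged:
            warnings.warn(
                f"sample {counts.sample_ids[k]!r}: fewer than {min_shared} genes shared "
                "with the reference; TMM factor set to 1",
                stacklevel=2,
            )
        factors[k] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def effective_library_sizes(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    design: StudyDesign | None = None,
) -> NormalizationFactors:
    """Effective library sizes ``N_k * factor_k`` and their median-scaled form.

    If ``design`` is given, the tissue offset ``ln(tissue_mg)`` is attached,
    aligned to the count matrix's sample order.
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    n = counts.library_sizes().astype(float)
    eff = n * factors
    scaled = eff / np.median(eff)
    offset = None
    if design is not None:
        offset = tissue_offsets(design.aligned_to(counts.sample_ids))
    return NormalizationFactors(
        sample_ids=list(counts.sample_ids),
        tmm_factor=factors,
        effective_library_size=eff,
        scaled_effective_library_size=scaled,
        tissue_offset=offset,
    )


def tissue_offsets(design: StudyDesign) -> np.ndarray:
    """Natural-log tissue weights, aligned to the design's sample order."""
    t = design.table["tissue_mg"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("tissue_mg must be finite and positive for the tissue-offset model")
    return np.log(t)
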