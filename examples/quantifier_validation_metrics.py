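"""Quantifier-validation metrics: family profiling and paired replicates.

Myosin heavy chain mRNAs expressed as fractions of their family total can
be compared with fiber-type protein fractions without any between-sample
normalization; paired baseline biopsies (two legs, untrained) bound the
technical variation of a quantification pipeline.
"""

import numpy as np
import pandas as pd

from offsetdge import (
    CountMatrix,
    StudyDesign,
    family_fractions,
    paired_log_differences,
    profile_correlation,
)
from offsetdge.validation import FamilyProfile

rng = np.random.default_rng(5)
n = 20

# --- myosin family: mRNA counts whose fractions track protein fractions
protein_fracs = rng.dirichlet([6, 5, 2], size=n)  # type I, IIA, IIX
depth = rng.integers(5_000, 20_000, size=n)
mrna_fracs = protein_fracs * np.exp(rng.normal(0, 0.12, size=(n, 3)))
mrna_fracs /= mrna_fracs.sum(axis=1, keepdims=True)
counts = np.round(mrna_fracs * depth[:, None]).astype(int).T
cm = CountMatrix(["MYH7", "MYH2", "MYH1"], [f"s{i}" for i in range(n)], counts)

mrna = family_fractions(cm, ["MYH7", "MYH2", "MYH1"])
protein = FamilyProfile(
    ["type_I", "type_IIA", "type_IIX"], [f"s{i}" for i in range(n)], protein_fracs, []
)
corr = profile_correlation(mrna, protein)
print("mRNA-protein family-profile correlations:")
print(corr.to_string(index=False))

# --- paired baseline biopsies: stable genes, two legs, same participant
rows = []
for p in range(8):
    for leg, sets in (("left", "single"), ("right", "multiple")):
        rows.append(
            dict(sample_id=f"P{p}_{leg}", participant_id=f"P{p}", leg=leg,
                 sets=sets, time="w0", tissue_mg=2.5, library_size=1e6)
        )
design = StudyDesign(pd.DataFrame(rows))
stable = [f"HK{i}" for i in range(30)]
base = rng.integers(200, 2000, size=(30, 8))
left = rng.poisson(base)
right = rng.poisson(base)  # same expectation, independent technical noise
paired = CountMatrix(stable, design.sample_ids, np.dstack([left, right]).reshape(30, 16))
diffs = paired_log_differences(paired, design, stable)
mad = diffs["log2_difference"].abs().mean()
print(f"\npaired-replicate mean |log2 difference| over {len(diffs)} gene-pairs: {mad:.3f}")
print(
    "Member correlations near 1 say the quantification preserves fiber-type\n"
    "biology; the mean absolute paired difference is the pipeline's technical\n"
    "noise floor (pure counting noise here, ~0.05-0.1 log2)."
)
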