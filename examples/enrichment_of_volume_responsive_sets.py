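"""Recover a planted volume-responsive gene set with MSD/CERNO, GSEA and ORA.

A volume-response simulation plants +1 log2 effects in 10% of genes (an
"extracellular-matrix-like" module).  After tissue-offset fits, the module
is declared as one gene set among random decoys and tested three ways:
CERNO on the MSD ranking (direction-free), preranked GSEA on log2
fold-changes (directional), and hypergeometric ORA on the DE list.
"""

import numpy as np

from offsetdge import (
    GeneSetCollection,
    ModelSpec,
    call_de,
    enrich_all,
    fit_all,
    make_design,
    scenario_params,
    simulate_dataset,
)

params = scenario_params("volume-response", seed=11, genes=400, n_participants=25)
design = make_design(params)
counts, truth = simulate_dataset(design, params)

table = call_de(fit_all(counts, design, ModelSpec(strategy="tissue_offset"), seed=11))

rng = np.random.default_rng(11)
sets = {"ECM_LIKE": ("cc|planted volume-responsive module", frozenset(truth.de_gene_ids))}
for j in range(30):
    members = rng.choice(truth.gene_ids, size=40, replace=False)
    sets[f"DECOY_{j:02d}"] = ("cc|random decoy", frozenset(members))

result = enrich_all(
    table, GeneSetCollection(sets=sets), "timew2pre:setsmultiple", n_perm=2000, seed=11
)
top = result.nsmallest(5, "cerno_pval")[
    ["ID", "set_size", "cerno_pval", "cerno_auc", "gsea_nes", "gsea_pval", "ora_pval"]
]
print(top.to_string(index=False))
print(
    "\nThe planted module should rank first with a CERNO AUC well above 0.5\n"
    "and a positive NES (higher expression in the multiple-set leg); decoy\n"
    "sets should scatter around AUC 0.5 with unremarkable p-values."
)
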