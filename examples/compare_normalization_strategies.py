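"""Fit the three normalization strategies and compare volume-effect calls.

Per-gene NB GLMMs with participant random intercepts are fitted naively
(raw counts), with the effective library size as a covariate, and with the
tissue offset added.  On the null-amplification scenario no gene truly
differs between legs per unit tissue, so each model's volume-by-time
coefficient distribution exposes its bias.
"""

from offsetdge import ModelSpec, call_de, compare_strategies, fit_all, make_design, scenario_params, simulate_dataset

params = scenario_params("null-amplification", seed=7, genes=400, n_participants=25)
design = make_design(params)
counts, truth = simulate_dataset(design, params)

tables = {}
for strategy in ("naive", "lib_size", "tissue_offset"):
    t = fit_all(counts, design, ModelSpec(strategy=strategy), seed=7)
    tables[strategy] = call_de(t)

report = compare_strategies(tables)
print(report.summary())
print(
    "The naive model's negative volume-coefficient median is the spurious\n"
    "reverse dose-dependency (less tissue behind the multiple-set libraries).\n"
    "The library-size covariate removes the depth signal; the tissue offset\n"
    "then shifts the distribution towards the multiple-set leg by the\n"
    "between-leg total-RNA ratio (~ +0.11 log2)."
)
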