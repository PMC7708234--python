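"""Per-gene NB-GLMM fitting, inference, diagnostics and DE calling."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from offsetdge import (
    CountMatrix,
    ModelSpec,
    SimulationParams,
    StudyDesign,
    build_design_matrix,
    call_de,
    filter_low_expression,
    fit_all,
    fit_gene,
    lrt_vs_poisson,
    make_design,
    residual_uniformity,
    simulate_dataset,
)
from offsetdge.glmm import DesignBundle

from conftest import SEED


def intercept_bundle(n_participants: int, obs_per_participant: int) -> DesignBundle:
    n = n_participants * obs_per_participant
    gidx = np.repeat(np.arange(n_participants), obs_per_participant)
    return DesignBundle(
        X=np.ones((n, 1)),
        coef_names=["(Intercept)"],
        offset=np.zeros(n),
        group_idx=gidx,
        group_labels=[f"P{i}" for i in range(n_participants)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


def clean_params(**kw):
    """Generator configuration matching the GLMM's assumptions: no
    amplification, no sample-level disturbances."""
    ones = {(s, t): 1.0 for s in ("single", "multiple") for t in ("w0", "w2pre", "w2post", "w12")}
    defaults = dict(
        mrna_amplification=dict(ones),
        total_rna_amplification=dict(ones),
        depth_log_sd=0.0,
        rna_per_mg_log_sd=0.0,
        de_fraction=0.0,
        seed=SEED,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "strategy,mode,interaction,expected",
        [
            (
                "tissue_offset", "rested", True,
                ["(Intercept)", "timew2pre", "timew12", "log_eff_lib",
                 "timew2pre:setsmultiple", "timew12:setsmultiple"],
            ),
            ("naive", "rested", False, ["(Intercept)", "timew2pre", "timew12"]),
            (
                "lib_size", "acute", True,
                ["(Intercept)", "timew2post", "log_eff_lib", "timew2post:setsmultiple"],
            ),
        ],
    )
    def test_coefficient_names(self, strategy, mode, interaction, expected):
        params = clean_params(n_participants=3, genes=5)
        design = make_design(params)
        spec = ModelSpec(strategy=strategy, analysis_mode=mode, interaction=interaction)
        sub = design.restrict_times(spec.times)
        lib = None if strategy == "naive" else np.full(sub.n_samples, 1.1)
        dm = build_design_matrix(sub, spec, scaled_eff_lib=lib)
        assert dm.coef_names == expected

    def test_extra_time_level_rejected(self):
        design = make_design(clean_params(n_participants=3, genes=5))
        with pytest.raises(ValueError, match="outside"):
            build_design_matrix(design, ModelSpec(strategy="naive"))

    def test_acute_mode_forbids_tissue_offset(self):
        with pytest.raises(ValueError, match="acute"):
            ModelSpec(strategy="tissue_offset", analysis_mode="acute")

    def test_missing_library_sizes_rejected(self):
        design = make_design(clean_params(n_participants=3, genes=5))
        spec = ModelSpec(strategy="lib_size")
        with pytest.raises(ValueError, match="scaled_eff_lib"):
            build_design_matrix(design.restrict_times(spec.times), spec)


class TestFitGene:
    def test_constant_counts_recover_log_mean_with_boundary_variance(self):
        dm = intercept_bundle(4, 2)
        fit = fit_gene(np.full(8, 4.0), dm)
        assert fit.beta[0] == pytest.approx(np.log(4.0), abs=1e-3)
        assert fit.status == "boundary"
        assert fit.sigma_u < 1e-3

    def test_all_zero_counts_degenerate(self):
        fit = fit_gene(np.zeros(8), intercept_bundle(4, 2))
        assert fit.status == "degenerate"

    def test_laplace_matches_adaptive_quadrature(self):
        # 20 seeded small instances; Laplace coefficients within 0.02 of the
        # exact marginal-likelihood maximiser (64-node adaptive Gauss-Hermite)
        rng = np.random.default_rng(SEED)
        dm = intercept_bundle(6, 2)
        worst = 0.0
        for _ in range(20):
            u = rng.normal(0, 0.4, 6)
            mu = 20 * np.exp(u[dm.group_idx])
            y = rng.negative_binomial(5, 5 / (5 + mu))
            lap = fit_gene(y, dm, integrator="laplace")
            agq = fit_gene(y, dm, integrator="aghq", aghq_nodes=64)
            assert lap.ok and agq.ok
            worst = max(worst, np.max(np.abs(lap.beta - agq.beta)))
        assert worst <= 0.02

    def test_matches_glmmtmb_reference(self, tmp_path):
        try:
            subprocess.run(["Rscript", "--version"], capture_output=True, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript unavailable")
        params = clean_params(
            n_participants=8, genes=3, depth_log_sd=0.1, rna_per_mg_log_sd=0.1,
            baseline_log_mean_range=(np.log(40), np.log(400)),
        )
        design = make_design(params)
        cm, _ = simulate_dataset(design, params)
        spec = ModelSpec(strategy="tissue_offset")
        sub = design.restrict_times(spec.times)
        cc = cm.subset_samples(sub.sample_ids)
        from offsetdge.normalization import effective_library_sizes

        norm = effective_library_sizes(cc)
        dm = build_design_matrix(sub, spec, scaled_eff_lib=norm.scaled_effective_library_size)
        df = sub.table.copy()
        df["log_eff_lib"] = np.log(norm.scaled_effective_library_size)
        df["ln_tissue"] = np.log(df["tissue_mg"])
        for gi in range(cc.n_genes):
            df[f"y{gi}"] = cc.counts[gi]
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "d$i2 <- as.numeric(d$time=='w2pre'); d$i12 <- as.numeric(d$time=='w12')\n"
            "d$m <- as.numeric(d$sets=='multiple')\n"
            f"for (g in 0:{cc.n_genes - 1}) {{\n"
            "  d$y <- d[[paste0('y', g)]]\n"
            "  fit <- glmmTMB(y ~ i2 + i12 + log_eff_lib + I(i2*m) + I(i12*m)"
            " + (1|participant_id), offset=d$ln_tissue, family=nbinom2, data=d)\n"
            "  cat(fixef(fit)$cond, sigma(fit), '\\n')\n"
            "}\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.splitlines() if l.strip()]
        for gi, line in enumerate(lines):
            vals = np.array([float(x) for x in line.split()])
            fit = fit_gene(cc.counts[gi], dm)
            assert np.max(np.abs(fit.beta - vals[:-1])) < 0.02
            assert fit.theta == pytest.approx(vals[-1], rel=0.05)

    def test_planted_interaction_recovered(self):
        # every gene carries a +1 log2 volume-by-time effect; the mean
        # estimate across 200 genes should sit near ln 2 = 0.693
        params = clean_params(n_participants=25, genes=200, de_fraction=1.0, de_log2fc=1.0)
        design = make_design(params)
        cm, _ = simulate_dataset(design, params)
        table = fit_all(cm, design, ModelSpec(strategy="naive"), seed=SEED)
        est = table[table["coefficient"] == "timew2pre:setsmultiple"]["estimate"]
        assert 0.62 <= est.mean() <= 0.77

    def test_offset_shift_moves_only_intercept(self):
        rng = np.random.default_rng(SEED)
        dm = intercept_bundle(6, 4)
        dm.X = np.column_stack([np.ones(24), np.tile([0, 1, 0, 1], 6)])
        dm.coef_names = ["(Intercept)", "x"]
        y = rng.negative_binomial(8, 8 / (8 + 30), size=24)
        fit0 = fit_gene(y, dm)
        shifted = DesignBundle(
            X=dm.X, coef_names=dm.coef_names, offset=dm.offset + 1.7,
            group_idx=dm.group_idx, group_labels=dm.group_labels, sample_ids=dm.sample_ids,
        )
        fit1 = fit_gene(y, shifted)
        assert fit1.beta[0] == pytest.approx(fit0.beta[0] - 1.7, abs=1e-6)
        assert fit1.beta[1] == pytest.approx(fit0.beta[1], abs=1e-6)

    def test_constant_library_covariate_equals_naive(self):
        params = clean_params(n_participants=6, genes=4)
        design = make_design(params)
        cm, _ = simulate_dataset(design, params)
        spec_n = ModelSpec(strategy="naive")
        sub = design.restrict_times(spec_n.times)
        cc = cm.subset_samples(sub.sample_ids)
        dm_n = build_design_matrix(sub, spec_n)
        dm_l = build_design_matrix(
            sub, ModelSpec(strategy="lib_size"), scaled_eff_lib=np.ones(sub.n_samples)
        )
        for gi in range(cc.n_genes):
            fn = fit_gene(cc.counts[gi], dm_n)
            fl = fit_gene(cc.counts[gi], dm_l)
            keep = [i for i, c in enumerate(dm_l.coef_names) if c != "log_eff_lib"]
            # identical likelihoods up to the inert covariate; agreement is
            # limited by quasi-Newton termination, not by the model
            assert np.allclose(fl.beta[keep][1:], fn.beta[1:], atol=1e-5)


class TestPoissonLrt:
    def test_nb_likelihood_never_below_poisson(self):
        rng = np.random.default_rng(SEED)
        dm = intercept_bundle(6, 4)
        for _ in range(10):
            y = rng.poisson(20, size=24)
            fit = fit_gene(y, dm)
            p = lrt_vs_poisson(fit, y, dm)
            assert 0.0 <= p <= 1.0

    def test_boundary_null_calibration_on_poisson_data(self):
        rng = np.random.default_rng(SEED + 1)
        dm = intercept_bundle(12, 2)
        pvals = []
        for _ in range(200):
            y = rng.poisson(20, size=24)
            fit = fit_gene(y, dm)
            pvals.append(lrt_vs_poisson(fit, y, dm))
        assert np.mean(np.array(pvals) < 0.05) <= 0.10

    def test_power_under_severe_overdispersion(self):
        rng = np.random.default_rng(SEED + 2)
        dm = intercept_bundle(12, 2)
        theta = 0.5
        pvals = []
        for _ in range(200):
            y = rng.negative_binomial(theta, theta / (theta + 20), size=24)
            fit = fit_gene(y, dm)
            pvals.append(lrt_vs_poisson(fit, y, dm))
        assert np.mean(np.array(pvals) < 0.05) >= 0.95


class TestResidualUniformity:
    def test_self_consistency_calibration(self):
        # data drawn from the fitted model itself: the uniformity p-value is
        # uniform, so the rejection rate at 0.05 sits near nominal
        rng = np.random.default_rng(SEED + 3)
        dm = intercept_bundle(8, 3)
        u0 = rng.normal(0, 0.3, 8)
        mu0 = 25 * np.exp(u0[dm.group_idx])
        fit = fit_gene(rng.negative_binomial(6, 6 / (6 + mu0)), dm)
        assert fit.ok
        eta0 = dm.X @ fit.beta
        pvals = []
        for rep in range(200):
            u = rng.normal(0, fit.sigma_u, 8)
            mu = np.exp(eta0 + u[dm.group_idx])
            y = rng.negative_binomial(fit.theta, fit.theta / (fit.theta + mu))
            pvals.append(residual_uniformity(fit, y, dm, n_sim=250, seed=rep))
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09

    def test_detects_outlier_contamination(self):
        rng = np.random.default_rng(SEED + 4)
        dm = intercept_bundle(12, 4)
        n = 48
        pvals = []
        for rep in range(50):
            y = rng.negative_binomial(6, 6 / (6 + 25), size=n).astype(float)
            k = rng.choice(n, size=5, replace=False)  # ~10% outliers
            y[k] = np.round(y[k] * np.exp(rng.normal(2.5, 0.5, size=5)))
            fit = fit_gene(y, dm)
            if fit.ok:
                pvals.append(residual_uniformity(fit, y, dm, n_sim=250, seed=rep))
        assert np.median(pvals) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(SEED + 5)
        dm = intercept_bundle(6, 4)
        y = rng.negative_binomial(6, 6 / (6 + 25), size=24)
        fit = fit_gene(y, dm)
        p1 = residual_uniformity(fit, y, dm, n_sim=250, seed=11)
        p2 = residual_uniformity(fit, y, dm, n_sim=250, seed=11)
        assert p1 == p2


class TestFilterAndDe:
    def test_filter_examples(self):
        cm = CountMatrix(
            ["g1", "g2", "g3"],
            ["s1", "s2"],
            np.array([[2, 0], [1, 1], [0, 0]]),
        )
        # with N ~ 3 and 1 counts the CPM of a single count is huge; use the
        # forced-arithmetic fixture at N = 1e6 via padding gene
        pad = CountMatrix(
            ["g1", "g2", "g3", "pad"],
            ["s1", "s2"],
            np.array([[2, 0], [1, 1], [0, 0], [999997, 999999]]),
        )
        kept = filter_low_expression(pad, min_cpm=1.0, min_samples=2)
        assert kept.gene_ids == ["g2", "pad"]
        ident = filter_low_expression(pad, min_cpm=0.0, min_samples=2)
        assert ident.gene_ids == pad.gene_ids
        with pytest.raises(ValueError, match="filter"):
            filter_low_expression(cm, min_cpm=1e9, min_samples=2)

    def test_all_zero_gene_always_removed(self):
        cm = CountMatrix(["a", "z"], ["s1", "s2"], np.array([[5, 5], [0, 0]]))
        assert filter_low_expression(cm, min_cpm=0.5, min_samples=1).gene_ids == ["a"]

    def test_de_rule_and_bh_ties(self):
        base = {
            "normalization_model": "naive",
            "interaction_model": True,
            "coefficient": "timew2pre:setsmultiple",
            "convergence": "converged",
        }
        rows = [
            dict(base, ensemblid="g1", pvalue=0.002, log2fc=0.6),
            dict(base, ensemblid="g2", pvalue=0.0001, log2fc=0.4),
            dict(base, ensemblid="g3", pvalue=0.5, log2fc=1.2),
        ]
        out = call_de(pd.DataFrame(rows), lfc_threshold=0.5, alpha=0.05)
        flags = out.set_index("ensemblid")["de"]
        assert bool(flags["g1"]) is True  # |lfc| > 0.5 and padj small
        assert bool(flags["g2"]) is False  # significant but below the lfc bar
        assert bool(flags["g3"]) is False  # large lfc but not significant
        ties = pd.DataFrame(
            [dict(base, ensemblid=f"t{i}", pvalue=0.05, log2fc=1.0) for i in range(7)]
        )
        adj = call_de(ties)["pvalue_adjust"]
        assert np.allclose(adj, 0.05)

    def test_strict_lfc_threshold(self):
        base = {
            "normalization_model": "naive",
            "interaction_model": True,
            "coefficient": "t",
            "convergence": "converged",
        }
        row = pd.DataFrame([dict(base, ensemblid="g", pvalue=1e-6, log2fc=0.5)])
        assert not call_de(row)["de"].iloc[0]  # exactly 0.5 is not > 0.5


class TestFitAll:
    def test_table_shape_and_determinism(self):
        params = clean_params(n_participants=4, genes=12)
        design = make_design(params)
        cm, _ = simulate_dataset(design, params)
        spec = ModelSpec(strategy="naive")
        t1 = fit_all(cm, design, spec, seed=SEED)
        t2 = fit_all(cm, design, spec, seed=SEED)
        assert len(t1) == 12 * 5  # five coefficients in the rested interaction model
        pd.testing.assert_frame_equal(t1, t2)

    def test_nan_tissue_rejected_before_fitting(self, four_sample_design):
        df = four_sample_design.table.copy()
        df.loc[0, "tissue_mg"] = np.nan
        with pytest.raises(ValueError, match="tissue_mg"):
            StudyDesign(df)
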