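"""End-to-end orchestration: simulate/load -> filter -> normalize -> fit the
chosen normalization strategies -> DE -> enrichment, with a cross-strategy
comparison report.

Every stage logs one structured line (parameters, input sizes); all
randomness derives from the config seed, and rerunning an identical config
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as odio
from .datamodel import CountMatrix, StudyDesign
from .enrichment import enrich_all
from .glmm import MODEL_NAMES, ModelSpec, call_de, filter_low_expression, fit_all
from .normalization import effective_library_sizes
from .simulate import SCENARIOS, make_design, scenario_params, simulate_dataset

__all__ = ["PipelineConfig", "ComparisonReport", "run_pipeline", "compare_strategies"]

log = logging.getLogger("offsetdge")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Inputs, model options and output location for one pipeline run.

    Exactly one of ``scenario`` (synthetic data) or ``counts_path`` +
    ``design_path`` (real data) must be set.
    """

    output_dir: str = "offsetdge_out"
    # data source
    scenario: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    # simulation overrides (forwarded to SimulationParams)
    simulation: dict = field(default_factory=dict)
    # model options
    strategies: tuple[str, ...] = ("naive", "lib_size", "tissue_offset")
    analysis_mode: str = "rested"
    interaction: bool = True
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    ci_level: float = 0.95
    # filter options
    min_cpm: float = 1.0
    min_samples: int | None = None
    # enrichment options
    enrichment_coefficient: str | None = None
    n_perm: int = 10000
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        has_sim = self.scenario is not None
        has_real = self.counts_path is not None or self.design_path is not None
        if has_sim and has_real:
            raise ValueError("give either a simulation scenario or data paths, not both")
        if not has_sim and not (self.counts_path and self.design_path):
            raise ValueError("either scenario or counts_path+design_path is required")
        if has_sim and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        self.strategies = tuple(self.strategies)
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {self.schema_version}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["strategies"] = list(d["strategies"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        return cls(**d)


@dataclass
class ComparisonReport:
    """Cross-strategy DE summary mirroring a model-comparison figure:
    signed DE counts per strategy, the exclusive/shared overlap partition,
    and per-strategy log2 fold-change distribution summaries."""

    de_counts: pd.DataFrame  # model, coefficient, n_de, n_up, n_down
    overlaps: pd.DataFrame  # coefficient, member combination, exclusive count
    shifts: pd.DataFrame  # model, coefficient, median/q25/q75 of log2fc

    def summary(self) -> str:
        lines = ["Differential-expression comparison across normalization strategies", ""]
        for _, r in self.de_counts.iterrows():
            lines.append(
                f"  {r['normalization_model']:<36s} {r['coefficient']:<24s} "
                f"DE={int(r['n_de']):5d} (up {int(r['n_up'])}, down {int(r['n_down'])})"
            )
        lines.append("")
        for coef, grp in self.overlaps.groupby("coefficient", sort=False):
            lines.append(f"  overlap partition for {coef}:")
            for _, r in grp.iterrows():
                lines.append(f"    {r['models']:<60s} {int(r['n_exclusive']):5d}")
        lines.append("")
        for _, r in self.shifts.iterrows():
            lines.append(
                f"  {r['normalization_model']:<36s} {r['coefficient']:<24s} "
                f"median log2FC={r['median']:+.4f} (IQR {r['q25']:+.4f}..{r['q75']:+.4f})"
            )
        return "\n".join(lines) + "\n"


def compare_strategies(tables: dict[str, pd.DataFrame]) -> ComparisonReport:
    """Build a :class:`ComparisonReport` from per-strategy fit tables with DE
    flags.  Tables must share the gene universe and coefficient set."""
    universes = {
        name: frozenset(t["ensemblid"]) for name, t in tables.items()
    }
    if len(set(universes.values())) != 1:
        raise ValueError("fit tables do not share a gene universe")
    names = list(tables)
    coefs = None
    for t in tables.values():
        c = [c for c in t["coefficient"].unique() if c != "(Intercept)" and c != "log_eff_lib"]
        if coefs is None:
            coefs = c
    de_rows, shift_rows, overlap_rows = [], [], []
    for coef in coefs:
        de_sets = {}
        for name in names:
            t = tables[name]
            sub = t[(t["coefficient"] == coef)]
            sub_ok = sub[sub["convergence"].isin(["converged", "boundary"])]
            de = sub_ok[sub_ok["de"].astype(bool)]
            de_sets[name] = set(de["ensemblid"])
            de_rows.append(
                {
                    "normalization_model": MODEL_NAMES.get(name, name),
                    "coefficient": coef,
                    "n_de": len(de),
                    "n_up": int((de["log2fc"] > 0).sum()),
                    "n_down": int((de["log2fc"] < 0).sum()),
                }
            )
            shift_rows.append(
                {
                    "normalization_model": MODEL_NAMES.get(name, name),
                    "coefficient": coef,
                    "median": float(sub_ok["log2fc"].median()),
                    "q25": float(sub_ok["log2fc"].quantile(0.25)),
                    "q75": float(sub_ok["log2fc"].quantile(0.75)),
                }
            )
        # exclusive partition: genes DE in exactly this combination of models
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(de_sets[n] for n in combo))
                outside = set.union(set(), *(de_sets[n] for n in names if n not in combo))
                overlap_rows.append(
                    {
                        "coefficient": coef,
                        "models": "+".join(MODEL_NAMES.get(n, n) for n in combo),
                        "n_exclusive": len(inside - outside),
                    }
                )
    report = ComparisonReport(
        de_counts=pd.DataFrame(de_rows),
        overlaps=pd.DataFrame(overlap_rows),
        shifts=pd.DataFrame(shift_rows),
    )
    _check_partition(report, tables)
    return report


def _check_partition(report: ComparisonReport, tables: dict[str, pd.DataFrame]) -> None:
    # inclusion-exclusion: per-strategy totals must equal sums of exclusive cells
    for _, row in report.de_counts.iterrows():
        model, coef, total = row["normalization_model"], row["coefficient"], row["n_de"]
        cells = report.overlaps[
            (report.overlaps["coefficient"] == coef)
            & report.overlaps["models"].str.split("+").map(lambda ms: model in ms)
        ]["n_exclusive"].sum()
        if cells != total:
            raise AssertionError(
                f"overlap partition inconsistent for {model}/{coef}: {cells} != {total}"
            )


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Execute every enabled stage and persist all artifacts.

    Raises ``RuntimeError`` naming the failing stage; artifacts produced
    before the failure remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "load"
    try:
        if config.scenario is not None:
            stage = "simulate"
            params = scenario_params(config.scenario, seed=config.seed, **config.simulation)
            design = make_design(params)
            counts, truth = simulate_dataset(design, params)
            log.info(
                "stage=simulate scenario=%s genes=%d samples=%d seed=%d",
                config.scenario, counts.n_genes, counts.n_samples, config.seed,
            )
            odio.write_counts(counts, out / "counts.tsv")
            odio.write_design(design, out / "design.tsv")
            truth_df = pd.DataFrame(
                {
                    "gene_id": truth.gene_ids,
                    "baseline_log_mean": truth.baseline_log_mean,
                    "dispersion": truth.dispersion,
                    "planted_log2fc": truth.planted_log2fc,
                }
            )
            odio.write_table(truth_df, out / "truth_genes.tsv")
            odio.write_table(truth.samples, out / "truth_samples.tsv")
        else:
            counts = odio.read_counts(config.counts_path)
            design = odio.read_design(config.design_path)
            log.info(
                "stage=load counts=%s design=%s genes=%d samples=%d",
                config.counts_path, config.design_path, counts.n_genes, counts.n_samples,
            )

        stage = "filter"
        counts = filter_low_expression(
            counts, min_cpm=config.min_cpm, min_samples=config.min_samples, design=design
        )
        log.info("stage=filter min_cpm=%s kept_genes=%d", config.min_cpm, counts.n_genes)

        stage = "normalize"
        mode_times = ModelSpec(
            strategy="naive", analysis_mode=config.analysis_mode, interaction=config.interaction
        ).times
        design_mode = design.aligned_to(counts.sample_ids).restrict_times(mode_times)
        counts_mode = counts.subset_samples(design_mode.sample_ids)
        norm = effective_library_sizes(counts_mode, design=design_mode)
        odio.write_table(norm.to_frame(), out / "normalization_factors.tsv")
        log.info("stage=normalize samples=%d", len(norm.sample_ids))

        stage = "fit"
        tables = {}
        for strategy in config.strategies:
            spec = ModelSpec(
                strategy=strategy,
                analysis_mode=config.analysis_mode,
                interaction=config.interaction,
                ci_level=config.ci_level,
            )
            t = fit_all(counts_mode, design_mode, spec, norm=norm, seed=config.seed)
            t = call_de(t, lfc_threshold=config.lfc_threshold, alpha=config.alpha)
            tables[strategy] = t
            odio.write_table(t, out / f"gene_fits_{strategy}.tsv", schema="gene_fit")
            n_conv = (t["convergence"] == "converged").sum()
            log.info(
                "stage=fit strategy=%s rows=%d converged_rows=%d", strategy, len(t), n_conv
            )

        stage = "compare"
        report = compare_strategies(tables)
        odio.write_table(report.de_counts, out / "report_de_counts.tsv")
        odio.write_table(report.overlaps, out / "report_overlaps.tsv")
        odio.write_table(report.shifts, out / "report_shifts.tsv")
        (out / "report_summary.txt").write_text(report.summary(), encoding="utf-8")
        log.info("stage=compare strategies=%d", len(tables))

        if config.gmt_path is not None:
            stage = "enrich"
            sets = odio.read_gmt(config.gmt_path)
            coef = config.enrichment_coefficient
            if coef is None:
                non_ref = [t for t in mode_times if t != mode_times[0]]
                coef = (
                    f"time{non_ref[0]}:setsmultiple" if config.interaction else f"time{non_ref[0]}"
                )
            frames = [
                enrich_all(
                    tables[s], sets, coef,
                    n_perm=config.n_perm, seed=config.seed,
                    lfc_threshold=config.lfc_threshold, alpha=config.alpha,
                )
                for s in config.strategies
            ]
            enr = pd.concat(frames, ignore_index=True)
            odio.write_table(enr, out / "enrichment.tsv", schema="enrichment")
            log.info("stage=enrich coefficient=%s sets=%d rows=%d", coef, len(sets), len(enr))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
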