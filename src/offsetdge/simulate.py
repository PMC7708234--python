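"""Synthetic count data with the structure of a within-participant,
two-leg training study and its fixed-RNA-input confound.

The generator emulates a design in which each participant trains one leg
with a single set and the other with multiple sets per exercise, with
biopsies at four time points (w0, w2pre, w2post, w12).  Training increases
total RNA per mg of tissue (factor ``B``) and the global mRNA pool per mg
(factor ``A``).  Because every sequencing library is prepared from the same
RNA mass, the tissue represented in a library shrinks as ``1/B``, and the
mRNA available for sequencing scales as ``A/B`` — so library sizes rise with
training even though tissue input falls.  Raw counts therefore confound
per-tissue expression with the amount of tissue behind each library; the
recorded truth makes that confound recoverable.

Per-tissue concentration of gene g in sample s:

    c_gs = exp(b_g + u_i + delta_g * ln2 * planted(sets, time))

with per-gene baseline ``b_g``, participant random intercept
``u_i ~ N(0, sigma_u^2)`` and planted log2 volume-by-time effect
``delta_g``.  Expected counts are ``depth_s`` times gene g's share of the
library's mRNA pool; counts are NB2 draws with gene dispersion theta_g
(variance ``mu + mu^2/theta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import SETS_LEVELS, TIME_LEVELS, CountMatrix, StudyDesign

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "make_design",
    "simulate_dataset",
    "scenario_params",
    "SCENARIOS",
]

TRAINED_TIMES = ("w2pre", "w2post", "w12")


def _default_A() -> dict:
    # global mRNA per mg tissue, relative to w0 (per-tissue library-size
    # increases: low volume +43%/+53%, moderate +43%/+49% at weeks 2/12;
    # the acute sample inherits the week-2 rested factor)
    return {
        ("single", "w0"): 1.0,
        ("multiple", "w0"): 1.0,
        ("single", "w2pre"): 1.43,
        ("multiple", "w2pre"): 1.43,
        ("single", "w2post"): 1.43,
        ("multiple", "w2post"): 1.43,
        ("single", "w12"): 1.53,
        ("multiple", "w12"): 1.49,
    }


def _default_B() -> dict:
    # total RNA per mg tissue, relative to w0 (low +15%, moderate +24% at
    # both weeks); w2post inherits w2pre: total RNA cannot change within 1 h
    return {
        ("single", "w0"): 1.0,
        ("multiple", "w0"): 1.0,
        ("single", "w2pre"): 1.15,
        ("multiple", "w2pre"): 1.24,
        ("single", "w2post"): 1.15,
        ("multiple", "w2post"): 1.24,
        ("single", "w12"): 1.15,
        ("multiple", "w12"): 1.24,
    }


@dataclass
class SimulationParams:
    """Study conditions for the generator.

    Amplification factors ``mrna_amplification`` (A) and
    ``total_rna_amplification`` (B) are keyed by ``(sets, time)`` and equal
    1 at the reference time w0.  Tissue per library is the fixed RNA input
    divided by the sample's total RNA per mg (``baseline * B``);
    ``rna_per_mg_log_sd`` optionally adds per-biopsy lognormal variability
    to that yield (0 by default: tissue follows the design cells exactly).
    ``depth_log_sd`` is the lognormal variability of sequencing depth
    around its mean, which is proportional to the mRNA mass in the
    fixed-input library (``A/B``).
    """

    n_participants: int = 25
    genes: int = 2000
    baseline_log_mean_range: tuple[float, float] = (np.log(5.0), np.log(500.0))
    dispersion_range: tuple[float, float] = (5.0, 50.0)
    participant_sd: float = 0.3
    mrna_amplification: dict = field(default_factory=_default_A)
    total_rna_amplification: dict = field(default_factory=_default_B)
    rna_input_ng: float = 1000.0
    baseline_rna_per_mg_ng: float = 400.0
    rna_per_mg_log_sd: float = 0.0
    mean_depth: float = 3.0e5
    depth_log_sd: float = 0.15
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    de_times: tuple[str, ...] = TRAINED_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        for name, fac in (
            ("mrna_amplification", self.mrna_amplification),
            ("total_rna_amplification", self.total_rna_amplification),
        ):
            for (sets, time), v in fac.items():
                if sets not in SETS_LEVELS or time not in TIME_LEVELS:
                    raise ValueError(f"{name}: unknown key ({sets!r}, {time!r})")
                if v <= 0:
                    raise ValueError(f"{name} factors must be > 0")
                if time == "w0" and v != 1.0:
                    raise ValueError(f"{name} must equal 1 at the reference time w0")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated dataset."""

    gene_ids: list[str]
    baseline_log_mean: np.ndarray  # b_g, natural log
    dispersion: np.ndarray  # theta_g
    planted_log2fc: np.ndarray  # delta_g, per-tissue log2 scale; 0 for null genes
    participant_intercepts: pd.DataFrame  # u_gi, natural log; genes x participants
    samples: pd.DataFrame  # per sample: tissue_mg, depth, A, B, rna_per_mg

    @property
    def de_gene_ids(self) -> list[str]:
        return [g for g, d in zip(self.gene_ids, self.planted_log2fc) if d != 0.0]


def _factor_lookup(fac: dict, sets: str, time: str) -> float:
    return float(fac[(sets, time)])


def make_design(params: SimulationParams) -> StudyDesign:
    """One sample per participant x leg x time, with legs randomly allocated
    to single- or multiple-set training and tissue_mg derived from the fixed
    RNA input and each sample's total RNA yield per mg."""
    root = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(root.spawn(2)[0])
    rows = []
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        legs = ["left", "right"]
        sets_order = ["single", "multiple"]
        if rng.random() < 0.5:
            sets_order = sets_order[::-1]
        for leg, sets in zip(legs, sets_order):
            for time in TIME_LEVELS:
                b = _factor_lookup(params.total_rna_amplification, sets, time)
                a = _factor_lookup(params.mrna_amplification, sets, time)
                rna_per_mg = (
                    params.baseline_rna_per_mg_ng
                    * b
                    * np.exp(rng.normal(0.0, params.rna_per_mg_log_sd))
                )
                tissue_mg = params.rna_input_ng / rna_per_mg
                # expected depth: mRNA mass in the fixed-RNA-input library
                # scales as A/B; the realized depth is drawn at count time
                depth = params.mean_depth * (a / b)
                rows.append(
                    {
                        "sample_id": f"{pid}_{leg}_{time}",
                        "participant_id": pid,
                        "leg": leg,
                        "sets": sets,
                        "time": time,
                        "tissue_mg": tissue_mg,
                        "library_size": depth,
                        "A": a,
                        "B": b,
                        "rna_per_mg": rna_per_mg,
                    }
                )
    df = pd.DataFrame(rows)
    return StudyDesign(df)


def simulate_dataset(
    design: StudyDesign, params: SimulationParams
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a count matrix for ``design`` and record the generating truth.

    Expected count of gene g in sample s is ``depth_s`` times g's share of
    that library's mRNA pool; because shares are normalised, per-tissue
    amplification common to all genes never changes library composition —
    only library size and tissue_mg carry it.  Counts are NB2 draws with
    per-gene dispersion.
    """
    df = design.table
    for col in ("A", "B"):
        if col not in df.columns:
            raise ValueError(
                "design lacks simulation factor columns; use make_design or "
                "supply A/B per sample"
            )
    root = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(root.spawn(2)[1])

    g = params.genes
    gene_ids = [f"G{j + 1:05d}" for j in range(g)]
    lo, hi = params.baseline_log_mean_range
    b_g = rng.uniform(lo, hi, size=g)
    th_lo, th_hi = params.dispersion_range
    theta = np.exp(rng.uniform(np.log(th_lo), np.log(th_hi), size=g))
    delta = np.zeros(g)
    n_de = int(round(params.de_fraction * g))
    if n_de:
        de_idx = rng.choice(g, size=n_de, replace=False)
        delta[de_idx] = params.de_log2fc

    participants = sorted(df["participant_id"].unique())
    p_index = {pid: i for i, pid in enumerate(participants)}
    # per-gene, per-participant random intercepts (constant across that
    # participant's samples, independent across genes)
    u_mat = rng.normal(0.0, params.participant_sd, size=(g, len(participants)))
    p_of_sample = df["participant_id"].map(p_index).to_numpy()

    planted_on = (
        (df["sets"] == "multiple") & df["time"].isin(params.de_times)
    ).to_numpy()
    # natural-log concentration per mg: b_g + u_gi (+ delta*ln2 where planted)
    log_c = b_g[:, None] + u_mat[:, p_of_sample]
    log_c = log_c + (delta[:, None] * np.log(2.0)) * planted_on[None, :]
    c = np.exp(log_c)
    pool = c.sum(axis=0)
    shares = c / pool[None, :]
    # realized depth: the expected value from the design (proportional to
    # A/B) modulated by the sample's mRNA pool relative to baseline (planted
    # responses enlarge the pool of a fixed-mass library) and lognormal noise
    at_w0 = (df["time"] == "w0").to_numpy()
    pool_ref = pool[at_w0].mean() if at_w0.any() else pool.mean()
    eps = rng.normal(0.0, params.depth_log_sd, size=len(df))
    depth = df["library_size"].to_numpy(dtype=float) * (pool / pool_ref) * np.exp(eps)
    mu = depth[None, :] * shares
    p = theta[:, None] / (theta[:, None] + mu)
    counts = rng.negative_binomial(theta[:, None], p)

    truth = SimulationTruth(
        gene_ids=gene_ids,
        baseline_log_mean=b_g,
        dispersion=theta,
        planted_log2fc=delta,
        participant_intercepts=pd.DataFrame(u_mat, index=gene_ids, columns=participants),
        samples=df[
            ["sample_id", "participant_id", "leg", "sets", "time", "tissue_mg", "A", "B", "rna_per_mg"]
        ].assign(depth=depth),
    )
    cm = CountMatrix(gene_ids=gene_ids, sample_ids=df["sample_id"].tolist(), counts=counts)
    return cm, truth


def scenario_params(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Preset study conditions.

    ``null-amplification``
        Equal per-tissue mRNA amplification in both legs, volume-dependent
        total-RNA increases (hence tissue-use reductions of about -13%
        single-set vs -19% multiple-set), no planted gene effects.  This is
        the scenario in which raw counts show a spurious reverse
        dose-dependency.
    ``volume-response``
        Default amplification plus planted volume-by-time effects
        (``de_fraction`` of genes at ``de_log2fc`` log2 units, multiple-set
        leg at trained time points).
    ``acute``
        Planted effects confined to the post-exercise sample (w2post);
        amplification factors inherit the rested week-2 state.
    """
    if name == "null-amplification":
        A = _default_A()
        for sets in SETS_LEVELS:
            A[(sets, "w2pre")] = 1.43
            A[(sets, "w2post")] = 1.43
            A[(sets, "w12")] = 1.51
        params = SimulationParams(
            mrna_amplification=A, de_fraction=0.0, seed=seed
        )
    elif name == "volume-response":
        params = SimulationParams(seed=seed)
    elif name == "acute":
        params = SimulationParams(de_times=("w2post",), seed=seed)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return replace(params, **overrides) if overrides else params


SCENARIOS = ("null-amplification", "volume-response", "acute")
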