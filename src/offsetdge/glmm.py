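"""Per-gene negative-binomial GLMMs with participant random intercepts.

Model for one gene: counts y_s given participant effect u_i follow NB2 with
mean mu_s and dispersion theta (variance mu + mu^2/theta), with

    ln mu_s = x_s' beta + o_s + u_i,      u_i ~ Normal(0, sigma_u^2).

The offset o_s is ln(tissue_mg) under the tissue-offset strategy and zero
otherwise; strategies other than the naive one add ln(scaled effective
library size) as a freely estimated covariate.  The marginal likelihood is
integrated over u by a Laplace approximation (default) or by adaptive
Gauss-Hermite quadrature (the high-accuracy integrator used for
cross-checks), and maximised by quasi-Newton over (beta, ln theta,
ln sigma_u).  Wald inference uses the outer numerical Hessian with a normal
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .datamodel import ACUTE_TIMES, RESTED_TIMES, CountMatrix, StudyDesign
from .enrichment import msd as _msd
from .normalization import NormalizationFactors, effective_library_sizes

__all__ = [
    "ModelSpec",
    "GeneFit",
    "DesignBundle",
    "build_design_matrix",
    "fit_gene",
    "lrt_vs_poisson",
    "residual_uniformity",
    "fit_all",
    "filter_low_expression",
    "call_de",
    "MODEL_NAMES",
]

STRATEGIES = ("naive", "lib_size", "tissue_offset")

#: strategy -> normalization_model label used in result tables
MODEL_NAMES = {
    "naive": "naive",
    "lib_size": "lib_size_normalized",
    "tissue_offset": "tissue_offset_lib_size_normalized",
}

_LN_SIGMA_FLOOR = -10.0  # sigma_u clamped at exp(-10)
_LN_SIGMA_BOUNDARY = -6.0  # below exp(-6) the variance is indistinguishable from 0
_LN_SIGMA_CEIL = 3.0
_LN_THETA_BOUNDS = (-7.0, 12.0)


@dataclass
class ModelSpec:
    """Which normalization strategy and contrast structure to fit."""

    strategy: str = "tissue_offset"
    analysis_mode: str = "rested"  # "rested": w0 -> {w2pre, w12}; "acute": w2pre -> w2post
    interaction: bool = True
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.analysis_mode not in ("rested", "acute"):
            raise ValueError("analysis_mode must be 'rested' or 'acute'")
        if self.analysis_mode == "acute" and self.strategy == "tissue_offset":
            raise ValueError(
                "the tissue-offset strategy is not available in acute mode: tissue "
                "weights are unreliable over one hour (fluid shifts) and total RNA "
                "cannot change in that window"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def times(self) -> tuple[str, ...]:
        return RESTED_TIMES if self.analysis_mode == "rested" else ACUTE_TIMES

    @property
    def reference_time(self) -> str:
        return self.times[0]


@dataclass
class DesignBundle:
    """Fixed-effects matrix, offset, grouping and names for one model."""

    X: np.ndarray
    coef_names: list[str]
    offset: np.ndarray
    group_idx: np.ndarray  # 0..n_groups-1, contiguous per participant
    group_labels: list[str]
    sample_ids: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class GeneFit:
    """Result of one per-gene fit."""

    beta: np.ndarray
    coef_names: list[str]
    cov: np.ndarray | None
    theta: float
    sigma_u: float
    loglik: float
    status: str  # "converged" | "boundary" | "degenerate" | "failed"
    n_obs: int
    params: np.ndarray | None = None  # packed (beta, ln theta, ln sigma_u)

    @property
    def ok(self) -> bool:
        return self.status in ("converged", "boundary")

    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(len(self.beta), np.nan)
        return np.sqrt(np.diag(self.cov)[: len(self.beta)])


def build_design_matrix(
    design: StudyDesign,
    spec: ModelSpec,
    scaled_eff_lib: np.ndarray | None = None,
) -> DesignBundle:
    """Treatment-coded fixed-effects matrix for the requested model.

    The intercept is the reference cell (w0 rested, w2pre acute).  With the
    interaction flag, volume contrasts enter only as time x sets(multiple)
    terms — the legs are randomized, so no sets main effect exists at the
    reference time.  Strategies other than naive append one
    ``log_eff_lib`` column (``ln`` of the scaled effective library size);
    the tissue-offset strategy sets the offset to ``ln(tissue_mg)``.
    """
    df = design.table
    allowed = set(spec.times)
    extra = sorted(set(df["time"]) - allowed)
    if extra:
        raise ValueError(
            f"design contains time level(s) {extra} outside the "
            f"{spec.analysis_mode} analysis window {spec.times}; restrict first"
        )
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    non_ref = [t for t in spec.times if t != spec.reference_time]
    for t in non_ref:
        cols.append((df["time"] == t).to_numpy(dtype=float))
        names.append(f"time{t}")
    if spec.strategy != "naive":
        if scaled_eff_lib is None:
            raise ValueError(
                f"strategy {spec.strategy!r} needs scaled effective library sizes; "
                "pass scaled_eff_lib (see normalization.effective_library_sizes)"
            )
        lib = np.asarray(scaled_eff_lib, dtype=float)
        if lib.shape != (n,):
            raise ValueError("scaled_eff_lib length does not match the design")
        cols.append(np.log(lib))
        names.append("log_eff_lib")
    if spec.interaction:
        mult = (df["sets"] == "multiple").to_numpy(dtype=float)
        for t in non_ref:
            cols.append((df["time"] == t).to_numpy(dtype=float) * mult)
            names.append(f"time{t}:setsmultiple")
    if spec.strategy == "tissue_offset":
        t_mg = df["tissue_mg"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t_mg)) or np.any(t_mg <= 0):
            raise ValueError("tissue-offset strategy requires positive tissue_mg for every sample")
        offset = np.log(t_mg)
    else:
        offset = np.zeros(n)
    # contiguous group codes in order of first appearance
    labels: list[str] = []
    index: dict[str, int] = {}
    gidx = np.empty(n, dtype=np.int64)
    for k, pid in enumerate(df["participant_id"]):
        if pid not in index:
            index[pid] = len(labels)
            labels.append(pid)
        gidx[k] = index[pid]
    return DesignBundle(
        X=np.column_stack(cols),
        coef_names=names,
        offset=offset,
        group_idx=gidx,
        group_labels=labels,
        sample_ids=df["sample_id"].tolist(),
    )


# ---------------------------------------------------------------------------
# likelihood kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _make_kernels():
    def nb_laplace_nll(params, X, y, off, gptr, u, lgy, poisson):
        """Negative Laplace-approximate marginal log-likelihood.

        Observations must be sorted by group; ``gptr`` holds group start
        offsets.  ``u`` is a warm-start buffer of conditional modes, updated
        in place.  With ``poisson`` True the dispersion entry of ``params``
        is ignored and the conditional likelihood is Poisson.
        """
        p = X.shape[1]
        theta = math.exp(params[p]) if not poisson else 0.0
        ln_sigma = params[p + 1]
        sig2 = math.exp(2.0 * ln_sigma)
        n = y.shape[0]
        eta0 = np.empty(n)
        for s in range(n):
            acc = off[s]
            for j in range(p):
                acc += X[s, j] * params[j]
            if acc > 30.0:
                acc = 30.0
            elif acc < -30.0:
                acc = -30.0
            eta0[s] = acc
        total = 0.0
        n_groups = gptr.shape[0] - 1
        for i in range(n_groups):
            ui = u[i]
            lo = gptr[i]
            hi = gptr[i + 1]
            for _ in range(60):
                g = -ui / sig2
                h = -1.0 / sig2
                for s in range(lo, hi):
                    mu = math.exp(eta0[s] + ui)
                    if poisson:
                        g += y[s] - mu
                        h -= mu
                    else:
                        r = (y[s] + theta) * mu / (theta + mu)
                        g += y[s] - r
                        h -= r * theta / (theta + mu)
                step = -g / h
                if step > 2.0:
                    step = 2.0
                elif step < -2.0:
                    step = -2.0
                ui += step
                if abs(step) < 1e-11:
                    break
            u[i] = ui
            gll = 0.0
            H = 1.0 / sig2
            for s in range(lo, hi):
                e = eta0[s] + ui
                mu = math.exp(e)
                if poisson:
                    gll += y[s] * e - mu - lgy[s]
                    H += mu
                else:
                    gll += (
                        math.lgamma(y[s] + theta)
                        - math.lgamma(theta)
                        - lgy[s]
                        + theta * math.log(theta)
                        + y[s] * e
                        - (y[s] + theta) * math.log(theta + mu)
                    )
                    H += (y[s] + theta) * theta * mu / ((theta + mu) * (theta + mu))
            total += gll - ui * ui / (2.0 * sig2) - ln_sigma - 0.5 * math.log(H)
        return -total

    try:  # pragma: no cover - exercised implicitly
        import numba

        fast = numba.njit(nb_laplace_nll, fastmath=False, cache=True)
        # force a compile now so per-fit timing is flat
        fast(
            np.zeros(3),
            np.ones((2, 1)),
            np.array([1.0, 2.0]),
            np.zeros(2),
            np.array([0, 2], dtype=np.int64),
            np.zeros(1),
            np.array([0.0, math.log(2.0)]),
            False,
        )
        return fast
    except Exception:
        return nb_laplace_nll


_nll_kernel = _make_kernels()


def _aghq_nll(params, X, y, off, gptr, u, lgy, n_nodes=64):
    """Negative marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Centres and scales the quadrature at each group's conditional mode and
    curvature (obtained from the Laplace kernel's warm-start buffer).
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    p = X.shape[1]
    beta = params[:p]
    theta = math.exp(params[p])
    ln_sigma = params[p + 1]
    sig2 = math.exp(2.0 * ln_sigma)
    eta0 = np.clip(X @ beta + off, -30.0, 30.0)
    # refresh the modes
    _nll_kernel(params, X, y, off, gptr, u, lgy, False)
    total = 0.0
    n_groups = gptr.shape[0] - 1
    for i in range(n_groups):
        lo, hi = gptr[i], gptr[i + 1]
        ui = u[i]
        mu_hat = np.exp(eta0[lo:hi] + ui)
        H = 1.0 / sig2 + np.sum((y[lo:hi] + theta) * theta * mu_hat / (theta + mu_hat) ** 2)
        s_i = 1.0 / math.sqrt(H)
        uu = ui + math.sqrt(2.0) * s_i * nodes  # (n_nodes,)
        mu = np.exp(eta0[lo:hi, None] + uu[None, :])
        cll = np.sum(
            gammaln(y[lo:hi, None] + theta)
            - gammaln(theta)
            - lgy[lo:hi, None]
            + theta * math.log(theta)
            + y[lo:hi, None] * (eta0[lo:hi, None] + uu[None, :])
            - (y[lo:hi, None] + theta) * np.log(theta + mu),
            axis=0,
        )
        h = cll - uu**2 / (2.0 * sig2) - ln_sigma - 0.5 * math.log(2.0 * math.pi)
        # log( sqrt(2) s_i * sum w_k exp(nodes_k^2) exp(h_k) )
        a = h + nodes**2 + np.log(weights)
        amax = np.max(a)
        total += amax + math.log(np.sum(np.exp(a - amax))) + 0.5 * math.log(2.0) + math.log(s_i)
    return -total


def _prepare(y: np.ndarray, dm: DesignBundle):
    """Sort observations by group; return arrays the kernels expect."""
    order = np.argsort(dm.group_idx, kind="stable")
    ys = np.asarray(y, dtype=float)[order]
    Xs = np.ascontiguousarray(dm.X[order])
    offs = np.ascontiguousarray(dm.offset[order])
    gs = dm.group_idx[order]
    counts = np.bincount(gs, minlength=dm.n_groups)
    gptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    lgy = gammaln(ys + 1.0)
    return ys, Xs, offs, gptr, lgy, order


def _start_values(ys, Xs, offs, n_params):
    """Poisson GLM (IRLS, no random effect) for beta; moment start for theta."""
    p = Xs.shape[1]
    eta = np.log(ys + 0.5) - offs
    beta, *_ = np.linalg.lstsq(Xs, eta, rcond=None)
    for _ in range(25):
        eta = np.clip(Xs @ beta + offs, -30, 30)
        mu = np.exp(eta)
        z = (eta - offs) + (ys - mu) / mu
        W = mu
        XtW = Xs.T * W
        try:
            new = np.linalg.solve(XtW @ Xs, XtW @ z)
        except np.linalg.LinAlgError:
            new, *_ = np.linalg.lstsq(XtW @ Xs, XtW @ z, rcond=None)
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    m = float(np.mean(ys))
    v = float(np.var(ys))
    ln_theta = math.log(max(m * m / max(v - m, 0.1), 1e-3))
    ln_theta = min(max(ln_theta, _LN_THETA_BOUNDS[0] + 1), _LN_THETA_BOUNDS[1] - 1)
    start = np.zeros(n_params)
    start[:p] = beta
    start[p] = ln_theta
    start[p + 1] = math.log(0.25)
    return start


def _numerical_hessian(fun, x, free, step=1e-4):
    """Central-difference Hessian over the ``free`` coordinates."""
    idx = np.where(free)[0]
    k = len(idx)
    H = np.zeros((k, k))
    h = step * (1.0 + np.abs(x[idx]))
    for a in range(k):
        for b in range(a, k):
            xpp = x.copy(); xpp[idx[a]] += h[a]; xpp[idx[b]] += h[b]
            xpm = x.copy(); xpm[idx[a]] += h[a]; xpm[idx[b]] -= h[b]
            xmp = x.copy(); xmp[idx[a]] -= h[a]; xmp[idx[b]] += h[b]
            xmm = x.copy(); xmm[idx[a]] -= h[a]; xmm[idx[b]] -= h[b]
            H[a, b] = H[b, a] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[a] * h[b])
    return H, idx


def _newton_polish(fun, x, H, idx, max_steps=3):
    """Refine the optimum with damped Newton steps on the free coordinates."""
    x = x.copy()
    f0 = fun(x)
    for _ in range(max_steps):
        g = np.zeros(len(idx))
        h = 1e-6 * (1.0 + np.abs(x[idx]))
        for a, ia in enumerate(idx):
            xp = x.copy(); xp[ia] += h[a]
            xm = x.copy(); xm[ia] -= h[a]
            g[a] = (fun(xp) - fun(xm)) / (2 * h[a])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            # drop near-null directions (e.g. an unidentified covariate)
            step = np.linalg.pinv(H, rcond=1e-8) @ g
        if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 0.1:
            break
        xn = x.copy()
        xn[idx] -= step
        fn = fun(xn)
        # near the optimum the objective moves below evaluation noise; trust
        # the Newton step unless it clearly worsens the fit
        if fn <= f0 + 1e-8:
            x, f0 = xn, min(fn, f0)
        else:
            break
        if np.max(np.abs(step)) < 1e-9:
            break
    return x, -f0


def fit_gene(
    y: np.ndarray,
    dm: DesignBundle,
    integrator: str = "laplace",
    aghq_nodes: int = 64,
    restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> GeneFit:
    """Maximise the marginal NB2-GLMM likelihood for one gene.

    ``integrator`` is ``"laplace"`` (default) or ``"aghq"`` (adaptive
    Gauss-Hermite with ``aghq_nodes`` nodes, used as the high-accuracy
    cross-check).  Non-convergence triggers up to ``restarts`` refits from
    perturbed starting values; an all-zero response is reported as
    ``"degenerate"`` without fitting.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != dm.X.shape[0]:
        raise ValueError("response length does not match the design")
    p = dm.X.shape[1]
    names = list(dm.coef_names)
    if not np.any(y > 0):
        return GeneFit(
            beta=np.full(p, np.nan), coef_names=names, cov=None, theta=np.nan,
            sigma_u=np.nan, loglik=np.nan, status="degenerate", n_obs=y.shape[0],
        )
    ys, Xs, offs, gptr, lgy, _ = _prepare(y, dm)
    u = np.zeros(dm.n_groups)

    if integrator == "laplace":
        def nll(params):
            return _nll_kernel(params, Xs, ys, offs, gptr, u, lgy, False)
    elif integrator == "aghq":
        def nll(params):
            return _aghq_nll(params, Xs, ys, offs, gptr, u, lgy, n_nodes=aghq_nodes)
    else:
        raise ValueError(f"unknown integrator {integrator!r}")

    bounds = [(None, None)] * p + [_LN_THETA_BOUNDS, (_LN_SIGMA_FLOOR, _LN_SIGMA_CEIL)]
    start = _start_values(ys, Xs, offs, p + 2)
    if rng is None:
        rng = np.random.default_rng(0)

    best = None
    x0 = start
    for attempt in range(restarts + 1):
        u[:] = 0.0
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, jac="3-point",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and res.success and np.isfinite(res.fun):
            break
        x0 = start + rng.normal(0.0, 0.3, size=start.shape)
    if best is None or not np.isfinite(best.fun):
        return GeneFit(
            beta=np.full(p, np.nan), coef_names=names, cov=None, theta=np.nan,
            sigma_u=np.nan, loglik=np.nan, status="failed", n_obs=y.shape[0],
        )
    xhat = best.x
    sigma_at_floor = xhat[p + 1] <= _LN_SIGMA_BOUNDARY
    theta_at_bound = (
        xhat[p] >= _LN_THETA_BOUNDS[1] - 1e-3 or xhat[p] <= _LN_THETA_BOUNDS[0] + 1e-3
    )
    at_bound = sigma_at_floor or theta_at_bound
    status = "boundary" if at_bound else ("converged" if best.success else "failed")
    if status == "failed":
        return GeneFit(
            beta=xhat[:p], coef_names=names, cov=None, theta=math.exp(xhat[p]),
            sigma_u=math.exp(xhat[p + 1]), loglik=-best.fun, status="failed",
            n_obs=y.shape[0], params=xhat,
        )
    free = np.ones(p + 2, dtype=bool)
    if sigma_at_floor:
        free[p + 1] = False
    if theta_at_bound:
        free[p] = False
    u[:] = 0.0
    H, idx = _numerical_hessian(nll, xhat, free)
    # one interior-point Newton polish: the quasi-Newton stop leaves ~1e-5
    # slack on the coefficients, which matters for exact-invariance contracts
    xhat, best_fun = _newton_polish(nll, xhat, H, idx)
    cov_full = np.full((p + 2, p + 2), np.nan)
    try:
        Hinv = np.linalg.inv(H)
        if np.any(np.diag(Hinv)[: min(p, len(idx))] <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
        bad = np.diag(Hinv) <= 0
        if bad.all():
            status = "failed"
            Hinv = None
        elif bad.any():
            # unidentified directions (e.g. a constant covariate column):
            # inference undefined for those coefficients only
            Hinv = Hinv.copy()
            Hinv[bad, :] = np.nan
            Hinv[:, bad] = np.nan
    if Hinv is not None:
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                cov_full[ia, ib] = Hinv[a, b]
    return GeneFit(
        beta=xhat[:p], coef_names=names,
        cov=cov_full if Hinv is not None else None,
        theta=math.exp(xhat[p]), sigma_u=math.exp(xhat[p + 1]),
        loglik=best_fun, status=status, n_obs=y.shape[0], params=xhat,
    )


def lrt_vs_poisson(fit: GeneFit, y: np.ndarray, dm: DesignBundle) -> float:
    """Boundary-corrected likelihood-ratio p-value of NB2 against Poisson.

    The Poisson model is the theta -> infinity boundary of NB2, so the null
    distribution of 2*(llNB - llPois) is the mixture 0.5*chi2_0 + 0.5*chi2_1.
    """
    if not fit.ok:
        raise ValueError("LRT needs a converged NB fit")
    y = np.asarray(y, dtype=float)
    ys, Xs, offs, gptr, lgy, _ = _prepare(y, dm)
    p = dm.X.shape[1]
    u = np.zeros(dm.n_groups)

    def nll_pois(params_red):
        params = np.concatenate([params_red[:p], [0.0], params_red[p:]])
        return _nll_kernel(params, Xs, ys, offs, gptr, u, lgy, True)

    x0 = np.concatenate([fit.beta, [math.log(max(fit.sigma_u, 1e-4))]])
    bounds = [(None, None)] * p + [(_LN_SIGMA_FLOOR, _LN_SIGMA_CEIL)]
    res = optimize.minimize(
        nll_pois, x0, method="L-BFGS-B", bounds=bounds, jac="3-point",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        return float("nan")
    lrt = 2.0 * (fit.loglik - (-res.fun))
    if lrt <= 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt, df=1))


def residual_uniformity(
    fit: GeneFit,
    y: np.ndarray,
    dm: DesignBundle,
    n_sim: int = 250,
    seed: int = 0,
) -> float:
    """Simulation-based uniformity test of randomized quantile residuals.

    Simulates ``n_sim`` responses from the fitted model (new random-intercept
    draws included), places each observation's count within its simulated
    reference distribution (uniform-randomized within ties) and returns the
    exact Kolmogorov-Smirnov p-value against Uniform(0, 1).
    """
    if not fit.ok:
        raise ValueError("uniformity test needs a converged fit")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    eta0 = np.clip(dm.X @ fit.beta + dm.offset, -30, 30)
    usim = rng.normal(0.0, fit.sigma_u, size=(n_sim, dm.n_groups))
    mu = np.exp(eta0[None, :] + usim[:, dm.group_idx])
    psucc = fit.theta / (fit.theta + mu)
    ysim = rng.negative_binomial(fit.theta, psucc)
    below = (ysim < y[None, :]).sum(axis=0)
    ties = (ysim == y[None, :]).sum(axis=0)
    r = (below + rng.uniform(0.0, 1.0, size=n) * (ties + 1)) / (n_sim + 1)
    return float(stats.kstest(r, "uniform", method="exact").pvalue)


def filter_low_expression(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    design: StudyDesign | None = None,
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to the size of the smallest (sets, time) cell of
    ``design``.
    """
    if min_cpm < 0:
        raise ValueError("min_cpm must be >= 0")
    if min_samples is None:
        if design is None:
            raise ValueError("give min_samples or a design to derive it from")
        min_samples = int(design.table.groupby(["sets", "time"]).size().min())
    cpm = counts.cpm()
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "expression filter removed every gene; lower min_cpm or min_samples"
        )
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    return CountMatrix(kept, counts.sample_ids, counts.counts[keep])


def fit_all(
    counts: CountMatrix,
    design: StudyDesign,
    spec: ModelSpec,
    norm: NormalizationFactors | None = None,
    seed: int = 0,
    compute_lrt: bool = False,
    compute_uniformity: bool = False,
    n_sim_uniformity: int = 250,
) -> pd.DataFrame:
    """Fit every gene under one model specification; return a tidy fit table.

    The design is restricted to the analysis mode's time points and aligned
    to the count matrix.  Normalization factors are computed from the full
    matrix unless supplied.  Failures are recorded per gene in the
    ``convergence`` column, never raised.  Estimates are on the natural-log
    scale; ``log2fc`` is estimate/ln(2) and ``msd`` the minimum significant
    difference on the log2 scale at the spec's CI level.
    """
    design = design.aligned_to(counts.sample_ids)
    keep = design.table["time"].isin(spec.times).to_numpy()
    sub_design = design.subset(keep)
    sub_counts = counts.subset_samples(sub_design.sample_ids)
    if spec.strategy == "tissue_offset" and sub_design.table["tissue_mg"].isna().any():
        raise ValueError("tissue_mg missing for the tissue-offset strategy")
    scaled = None
    if spec.strategy != "naive":
        if norm is None:
            norm = effective_library_sizes(sub_counts)
        lookup = dict(zip(norm.sample_ids, norm.scaled_effective_library_size))
        scaled = np.array([lookup[s] for s in sub_counts.sample_ids])
    dm = build_design_matrix(sub_design, spec, scaled_eff_lib=scaled)
    z_level = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    ln2 = math.log(2.0)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * sub_counts.n_genes, dtype=np.uint32)
    rows = []
    model_name = MODEL_NAMES[spec.strategy]
    for gi, gene in enumerate(sub_counts.gene_ids):
        y = sub_counts.counts[gi]
        rng = np.random.default_rng(int(child_seeds[2 * gi]))
        fit = fit_gene(y, dm, rng=rng)
        lrt_p = np.nan
        unif_p = np.nan
        if fit.ok and compute_lrt:
            lrt_p = lrt_vs_poisson(fit, y, dm)
        if fit.ok and compute_uniformity:
            unif_p = residual_uniformity(
                fit, y, dm, n_sim=n_sim_uniformity, seed=int(child_seeds[2 * gi + 1])
            )
        ses = fit.se()
        for ci, cname in enumerate(dm.coef_names):
            est = fit.beta[ci] if fit.ok else np.nan
            se = ses[ci] if fit.ok else np.nan
            z = est / se if fit.ok and se > 0 else np.nan
            pval = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            l2 = est / ln2 if np.isfinite(est) else np.nan
            se2 = se / ln2 if np.isfinite(se) else np.nan
            rows.append(
                {
                    "ensemblid": gene,
                    "normalization_model": model_name,
                    "interaction_model": bool(spec.interaction),
                    "coefficient": cname,
                    "estimate": est,
                    "se": se,
                    "zvalue": z,
                    "pvalue": pval,
                    "pvalue_adjust": np.nan,
                    "log2fc": l2,
                    "msd": _msd(l2, se2, level=spec.ci_level)
                    if np.isfinite(l2) and np.isfinite(se2) and se2 > 0
                    else np.nan,
                    "convergence": fit.status,
                    "de": False,
                    "theta": fit.theta,
                    "sigma_u": fit.sigma_u,
                    "loglik": fit.loglik,
                    "poisson_lrt_pvalue": lrt_p,
                    "uniformity_pvalue": unif_p,
                }
            )
    table = pd.DataFrame(rows)
    # keep z at the stated level available downstream without refitting
    table.attrs["ci_level"] = spec.ci_level
    table.attrs["z_level"] = float(z_level)
    return table


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def call_de(
    table: pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust per (model, interaction, coefficient) stratum
    and flag differential expression.

    A gene-coefficient is DE when ``|log2fc| > lfc_threshold`` (strict) and
    the adjusted p-value is below ``alpha``.  Non-converged and degenerate
    rows contribute no hypothesis and keep NaN adjusted p-values.
    """
    out = table.copy()
    out["pvalue_adjust"] = np.nan
    out["de"] = False
    ok = out["convergence"].isin(["converged", "boundary"]) & out["pvalue"].notna()
    for _, idx in out[ok].groupby(
        ["normalization_model", "interaction_model", "coefficient"], sort=False
    ).groups.items():
        adj = _bh(out.loc[idx, "pvalue"].to_numpy())
        out.loc[idx, "pvalue_adjust"] = adj
    out.loc[ok, "de"] = (out.loc[ok, "log2fc"].abs() > lfc_threshold) & (
        out.loc[ok, "pvalue_adjust"] < alpha
    )
    return out
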