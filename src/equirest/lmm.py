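"""Gaussian linear mixed models with crossed horse and calendar-date intercepts.

Model
-----
For the log-transformed outcome :math:`y_{hdw}` of horse *h* on date *d* in
window *w* (day/night) under condition *c(h,d)*,

.. math::

    \\log(y + c) = \\mu_{c,w} + a_h + b_d + \\varepsilon, \\qquad
    a_h \\sim N(0, \\sigma^2_H),\\;
    b_d \\sim N(0, \\sigma^2_D),\\;
    \\varepsilon \\sim N(0, \\sigma^2),

with a full condition x window cell-mean structure (6 cells) for the fixed
part and *crossed* random intercepts: every horse appears on many dates and
every date carries several horses.  Back-transformed contrasts of cell means
are reported as multiplicative factors ("lying duration higher at night by a
factor of F").

Estimation profiles the deviance over the variance ratios
:math:`\\gamma_k = \\sigma^2_k / \\sigma^2`: for fixed ratios the fixed
effects and the residual variance have closed forms via the penalized
mixed-model equations, leaving a two-parameter bounded optimization.  Both ML
and REML criteria are available; fits with flat priors coincide numerically
with penalized Bayesian point estimates away from the variance boundary.

Inference is by parametric bootstrap: likelihood-ratio tests simulate
response data from the fitted null model and refit both models per replicate
(:func:`pb_test`), and confidence intervals simulate from the fitted full
model and take percentile intervals of the back-transformed contrast
(:func:`pb_confint`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

CONDITION_LEVELS: tuple[str, ...] = ("BOX", "ALONE", "PAIRS")
WINDOW_LEVELS: tuple[str, ...] = ("DAY", "NIGHT")
CELLS: tuple[tuple[str, str], ...] = tuple((c, w) for c in CONDITION_LEVELS for w in WINDOW_LEVELS)

_LOG2PI = float(np.log(2.0 * np.pi))

#: smallest lying run (s) that survives 31-sample majority smoothing; sets the
#: smallest observable nonzero lying_h_per_h increment
_MIN_LYING_RUN_S = 16.0

TERMS = ("GLOBAL", "CONDITION", "WINDOW", "INTERACTION")
_TERM_MODELS = {
    "GLOBAL": ("full", "window"),
    "CONDITION": ("additive", "window"),
    "WINDOW": ("additive", "condition"),
    "INTERACTION": ("full", "additive"),
}


class SingularDesignError(ValueError):
    """Raised when a fixed-effect design cell is empty."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome column, log offset, bootstrap settings."""

    outcome: str = "lying_h_per_h"
    offset: float | str = "auto"
    coding: str = "cell_means"  # or "treatment"
    ci_level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.coding not in ("cell_means", "treatment"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")


@dataclass
class FitResult:
    """Point estimates on the log scale plus variance components."""

    beta: pd.Series
    sigma2_horse: float
    sigma2_date: float
    sigma2_resid: float
    loglik: float
    converged: bool
    method: str
    offset: float
    outcome: str
    coding: str
    n_obs: int
    _state: dict = field(default_factory=dict, repr=False)

    def cell_means(self) -> pd.DataFrame:
        """6 fitted cell means (log scale), conditions x windows."""
        mu = np.empty((len(CONDITION_LEVELS), len(WINDOW_LEVELS)))
        for i, c in enumerate(CONDITION_LEVELS):
            for j, w in enumerate(WINDOW_LEVELS):
                mu[i, j] = _cell_mean_from_beta(self.beta, self.coding, c, w)
        return pd.DataFrame(mu, index=list(CONDITION_LEVELS), columns=list(WINDOW_LEVELS))


@dataclass
class ContrastResult:
    """A fixed-effect contrast reported on the multiplicative factor scale."""

    name: str
    log_estimate: float
    factor: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_boot_used: int = 0

    def __str__(self) -> str:
        s = f"{self.name}: by a factor of {self.factor:.2f}"
        if self.ci_low is not None:
            s += f" [{self.ci_low:.2f}-{self.ci_high:.2f}]"
        if self.p_value is not None:
            s += f" (p = {self.p_value:.3g})"
        return s


# ---------------------------------------------------------------------------
# design matrices


def _levels_check(df: pd.DataFrame) -> None:
    for col, levels in (("condition", CONDITION_LEVELS), ("window", WINDOW_LEVELS)):
        extra = set(df[col].unique()) - set(levels)
        if extra:
            raise ValueError(f"unknown {col} levels {sorted(extra)}")


def build_fixed_design(df: pd.DataFrame, terms: str = "full", coding: str = "cell_means"):
    """Fixed-effect design matrix for the requested mean structure.

    ``terms``: 'full' (condition x window), 'additive' (condition + window),
    'condition', 'window', or 'intercept'.  Cell-means coding is only defined
    for the full model; nested models use treatment (reference BOX / DAY)
    coding.
    """
    cond = df["condition"].to_numpy()
    win = df["window"].to_numpy()
    n = len(df)
    if terms == "full" and coding == "cell_means":
        cols = [f"{c}:{w}" for c, w in CELLS]
        X = np.zeros((n, 6))
        for k, (c, w) in enumerate(CELLS):
            X[:, k] = (cond == c) & (win == w)
        return X, cols

    cols = ["Intercept"]
    blocks = [np.ones((n, 1))]
    if terms in ("full", "additive", "condition"):
        for c in CONDITION_LEVELS[1:]:
            blocks.append((cond == c).astype(float)[:, None])
            cols.append(f"condition[{c}]")
    if terms in ("full", "additive", "window"):
        for w in WINDOW_LEVELS[1:]:
            blocks.append((win == w).astype(float)[:, None])
            cols.append(f"window[{w}]")
    if terms == "full":
        for c in CONDITION_LEVELS[1:]:
            for w in WINDOW_LEVELS[1:]:
                blocks.append(((cond == c) & (win == w)).astype(float)[:, None])
                cols.append(f"condition[{c}]:window[{w}]")
    if terms == "intercept":
        pass
    elif terms not in ("full", "additive", "condition", "window"):
        raise ValueError(f"unknown terms {terms!r}")
    return np.hstack(blocks), cols


def _cell_mean_from_beta(beta: pd.Series, coding: str, c: str, w: str) -> float:
    if coding == "cell_means":
        return float(beta[f"{c}:{w}"])
    mu = float(beta["Intercept"])
    if c != CONDITION_LEVELS[0]:
        mu += float(beta.get(f"condition[{c}]", 0.0))
    if w != WINDOW_LEVELS[0]:
        mu += float(beta.get(f"window[{w}]", 0.0))
    key = f"condition[{c}]:window[{w}]"
    if c != CONDITION_LEVELS[0] and w != WINDOW_LEVELS[0]:
        mu += float(beta.get(key, 0.0))
    return mu


def _random_design(df: pd.DataFrame):
    horses, zh = np.unique(df["horse_id"].astype(str), return_inverse=True)
    dates, zd = np.unique(df["date"].astype(str), return_inverse=True)
    n = len(df)
    Zh = np.zeros((n, horses.size))
    Zh[np.arange(n), zh] = 1.0
    Zd = np.zeros((n, dates.size))
    Zd[np.arange(n), zd] = 1.0
    return (list(horses), Zh), (list(dates), Zd)


# ---------------------------------------------------------------------------
# profiled deviance machinery


class _LMMProblem:
    """Precomputed cross-products for one (X, Z_horse, Z_date) design.

    The profiled deviance for variance ratios gamma_k = sigma2_k / sigma2 is
    evaluated from the penalized mixed-model equations in the scaled
    coordinates u* = Lambda^{-1/2} u, so the gamma -> 0 boundary is exact and
    every evaluation costs one Cholesky of a (q+p) x (q+p) matrix, with
    q = n_horses + n_dates.  Refitting the same design to a new response
    (bootstrap replicates) only updates the right-hand-side vectors.
    """

    def __init__(self, X: np.ndarray, Zh: np.ndarray, Zd: np.ndarray):
        self.X = X
        self.n, self.p = X.shape
        self.qh = Zh.shape[1]
        self.qd = Zd.shape[1]
        self.q = self.qh + self.qd
        Z = np.hstack([Zh, Zd])
        self.comp = np.concatenate([np.zeros(self.qh, int), np.ones(self.qd, int)])
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.XtX = X.T @ X
        self.Z = Z
        # reusable (q+p)^2 buffer
        self._C = np.empty((self.q + self.p, self.q + self.p))

    def rhs(self, y: np.ndarray):
        return self.Z.T @ y, self.X.T @ y, float(y @ y)

    def deviance(self, s: np.ndarray, rhs, reml: bool):
        """-2 log(likelihood) profiled over beta and sigma2 at ratios gamma = s**2.

        Returns (criterion, beta, u, prss, logdet_V, logdet_XVX).
        """
        Zty, Xty, yty = rhs
        sfull = s[self.comp]
        q, p, n = self.q, self.p, self.n
        C = self._C
        C[:q, :q] = self.ZtZ * np.outer(sfull, sfull)
        C[:q, :q][np.diag_indices(q)] += 1.0
        C[:q, q:] = sfull[:, None] * self.ZtX
        C[q:, :q] = C[:q, q:].T
        C[q:, q:] = self.XtX
        a = np.concatenate([sfull * Zty, Xty])
        try:
            L, low = linalg.cho_factor(C, lower=True, overwrite_a=False, check_finite=False)
        except linalg.LinAlgError:
            # large finite penalty keeps finite-difference gradients defined
            return 1e12, None, None, np.inf, np.nan, np.nan
        theta = linalg.cho_solve((L, low), a, check_finite=False)
        prss = yty - a @ theta
        prss = max(prss, 1e-300)
        d = np.log(np.diag(L))
        logdet_V = 2.0 * float(d[:q].sum())
        logdet_XVX = 2.0 * float(d[q:].sum())
        if reml:
            df = n - p
            crit = logdet_V + logdet_XVX + df * (1.0 + _LOG2PI + np.log(prss / df))
        else:
            crit = logdet_V + n * (1.0 + _LOG2PI + np.log(prss / n))
        beta = theta[q:]
        u = sfull * theta[:q]
        return crit, beta, u, prss, logdet_V, logdet_XVX

    def fit(self, y: np.ndarray, reml: bool = True, start: np.ndarray | None = None):
        """Optimize the profiled criterion over s = sqrt(gamma) >= 0."""
        rhs = self.rhs(y)

        def objective(s):
            return self.deviance(np.asarray(s), rhs, reml)[0]

        s0 = np.asarray(start, dtype=float) if start is not None else np.array([1.0, 1.0])
        s0 = np.clip(s0, 0.0, 50.0)
        bounds = [(0.0, 1e6), (0.0, 1e6)]
        res = optimize.minimize(
            objective,
            s0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        s = np.abs(res.x)
        # polish: the boundary can trap L-BFGS-B when started far away
        if start is None:
            alt = optimize.minimize(
                objective, np.array([0.05, 0.05]), method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 200, "ftol": 1e-12},
            )
            if alt.fun < res.fun - 1e-10:
                res, s = alt, np.abs(alt.x)
        if not res.success:
            # line-search breakdowns near the variance boundary: derivative-free polish
            nm = optimize.minimize(
                objective, s, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 400},
            )
            if nm.fun <= res.fun:
                # the criterion depends on s only through gamma = s**2
                res, s = nm, np.abs(nm.x)
        crit, beta, u, prss, *_ = self.deviance(s, rhs, reml)
        df = self.n - self.p if reml else self.n
        sigma2 = prss / df
        return {
            "s": s,
            "gamma": s**2,
            "sigma2": sigma2,
            "sigma2_horse": s[0] ** 2 * sigma2,
            "sigma2_date": s[1] ** 2 * sigma2,
            "beta": beta,
            "u": u,
            "loglik": -0.5 * crit,
            "criterion": crit,
            "converged": bool(res.success),
            "reml": reml,
        }


def _auto_offset(df: pd.DataFrame, outcome: str) -> float:
    """Half the smallest observable nonzero outcome value, given window length.

    For bout counts the smallest nonzero value is one bout over the longest
    observed window; for lying duration it is the shortest lying run that
    survives 31 s majority smoothing (16 s) over that window.  If the data
    carry no ``observed_h`` column, half the smallest positive observed value
    is used instead.  An offset is only needed when zeros occur (some horses
    never lay down in some day windows); with strictly positive outcomes the
    offset is zero and the transform is a plain log.
    """
    y = df[outcome].to_numpy(dtype=float)
    if (y > 0).all():
        return 0.0
    if "observed_h" in df.columns:
        h_max = float(df["observed_h"].max())
        if outcome == "n_bouts_per_h":
            return 0.5 * (1.0 / h_max)
        if outcome == "lying_h_per_h":
            return 0.5 * (_MIN_LYING_RUN_S / 3600.0) / h_max
    pos = y[y > 0]
    if pos.size == 0:
        raise ValueError(f"outcome {outcome!r} is identically zero")
    return 0.5 * float(pos.min())


def _prepare(df: pd.DataFrame, spec: ModelSpec, terms: str = "full"):
    df = df.copy()
    if "calendar_date" in df.columns and "date" not in df.columns:
        df = df.rename(columns={"calendar_date": "date"})
    for col in ("condition", "window", "horse_id", "date", spec.outcome):
        if col not in df.columns:
            raise ValueError(f"data is missing column {col!r}")
    _levels_check(df)
    if df["horse_id"].nunique() < 2 or df["date"].nunique() < 2:
        raise ValueError("need at least 2 horses and 2 dates for crossed random effects")

    cells = df.groupby(["condition", "window"]).size()
    for c, w in CELLS:
        if (c, w) not in cells.index:
            raise SingularDesignError(f"design cell condition={c}, window={w} has no observations")

    offset = _auto_offset(df, spec.outcome) if spec.offset == "auto" else float(spec.offset)
    y_raw = df[spec.outcome].to_numpy(dtype=float)
    if offset == 0.0 and not (y_raw > 0).all():
        raise ValueError("offset 0 requires strictly positive outcomes")
    ylog = np.log(y_raw + offset)

    coding = spec.coding if terms == "full" else "treatment"
    X, cols = build_fixed_design(df, terms=terms, coding=coding)
    (horses, Zh), (dates, Zd) = _random_design(df)
    problem = _LMMProblem(X, Zh, Zd)
    return df, problem, ylog, cols, offset, coding, horses, dates


def fit_lmm(data: pd.DataFrame, spec: ModelSpec = ModelSpec(), method: str = "REML",
            terms: str = "full") -> FitResult:
    """Fit the crossed random-intercepts model to a lying-metrics table.

    ``data`` needs columns ``horse_id, date, condition, window`` plus the
    outcome named in ``spec``.  Returns estimates on the log scale; use
    :func:`marginal_condition_contrasts` / :func:`pb_confint` for the
    factor-scale summaries.
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    df, problem, ylog, cols, offset, coding, horses, dates = _prepare(data, spec, terms)
    fit = problem.fit(ylog, reml=(method == "REML"))
    return FitResult(
        beta=pd.Series(fit["beta"], index=cols),
        sigma2_horse=float(fit["sigma2_horse"]),
        sigma2_date=float(fit["sigma2_date"]),
        sigma2_resid=float(fit["sigma2"]),
        loglik=float(fit["loglik"]),
        converged=fit["converged"],
        method=method,
        offset=offset,
        outcome=spec.outcome,
        coding=coding,
        n_obs=problem.n,
        _state={"problem": problem, "fit": fit, "df": df, "ylog": ylog, "terms": terms,
                "horses": horses, "dates": dates},
    )


def loglik_at(result: FitResult, sigma2_horse: float, sigma2_date: float, sigma2_resid: float) -> float:
    """Profile log-likelihood re-evaluated at given variance components."""
    problem: _LMMProblem = result._state["problem"]
    ylog = result._state["ylog"]
    s = np.sqrt(np.array([sigma2_horse, sigma2_date]) / sigma2_resid)
    crit = problem.deviance(s, problem.rhs(ylog), reml=(result.method == "REML"))[0]
    return -0.5 * crit


# ---------------------------------------------------------------------------
# contrasts


def _contrast_weights(name: str) -> np.ndarray:
    """Weights over the 6 cell means (CELLS order) for the named contrast."""
    w = np.zeros(6)
    idx = {cw: k for k, cw in enumerate(CELLS)}
    if name == "night_vs_day":
        for c in CONDITION_LEVELS:
            w[idx[(c, "NIGHT")]] += 1 / 3
            w[idx[(c, "DAY")]] -= 1 / 3
    elif name == "day_vs_night":
        return -_contrast_weights("night_vs_day")
    elif name in ("alone_vs_box", "pairs_vs_box"):
        c1 = "ALONE" if name == "alone_vs_box" else "PAIRS"
        for win in WINDOW_LEVELS:
            w[idx[(c1, win)]] += 1 / 2
            w[idx[("BOX", win)]] -= 1 / 2
    else:
        raise ValueError(f"unknown contrast {name!r}")
    return w


def _cell_mean_vector(result: FitResult) -> np.ndarray:
    cm = result.cell_means()
    return np.array([cm.loc[c, w] for c, w in CELLS])


def contrast_estimate(result: FitResult, contrast: str | np.ndarray) -> tuple[str, float]:
    w = _contrast_weights(contrast) if isinstance(contrast, str) else np.asarray(contrast, float)
    if w.shape != (6,):
        raise ValueError("a contrast is a weight vector over the 6 condition x window cells")
    name = contrast if isinstance(contrast, str) else "custom"
    return name, float(w @ _cell_mean_vector(result))


def marginal_condition_contrasts(result: FitResult) -> list[ContrastResult]:
    """Factor-scale condition contrasts (vs BOX, averaged over windows) and the
    night/day contrast (averaged over conditions), without intervals."""
    out = []
    for name in ("alone_vs_box", "pairs_vs_box", "night_vs_day"):
        _, est = contrast_estimate(result, name)
        out.append(ContrastResult(name=name, log_estimate=est, factor=float(np.exp(est))))
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap


def _simulate_responses(problem: _LMMProblem, fit: dict, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """n_boot response vectors drawn from the fitted model (rows = replicates)."""
    mean = problem.X @ fit["beta"]
    Zh = problem.Z[:, : problem.qh]
    Zd = problem.Z[:, problem.qh:]
    bh = rng.normal(0.0, np.sqrt(max(fit["sigma2_horse"], 0.0)), size=(n_boot, problem.qh))
    bd = rng.normal(0.0, np.sqrt(max(fit["sigma2_date"], 0.0)), size=(n_boot, problem.qd))
    eps = rng.normal(0.0, np.sqrt(fit["sigma2"]), size=(n_boot, problem.n))
    return mean[None, :] + bh @ Zh.T + bd @ Zd.T + eps


def pb_test(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    term: str = "CONDITION",
    n_boot: int | None = None,
    seed: int | None = None,
) -> dict:
    """Parametric-bootstrap likelihood-ratio test for one model term.

    Nested pairs (ML fits): GLOBAL = full vs window-only; CONDITION =
    additive vs window-only; WINDOW = additive vs condition-only;
    INTERACTION = full vs additive.  ``n_boot`` response vectors are drawn
    from the fitted null; ``p = (1 + #{LRT* >= LRT_obs}) / (n_boot + 1)``.
    """
    term = term.upper()
    if term not in _TERM_MODELS:
        raise ValueError(f"term must be one of {TERMS}")
    n_boot = int(n_boot if n_boot is not None else spec.n_boot)
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99 for a meaningful bootstrap p-value")
    seed = seed if seed is not None else spec.seed
    rng = np.random.default_rng(seed)

    full_terms, null_terms = _TERM_MODELS[term]
    df, prob_full, ylog, *_ = _prepare(data, spec, full_terms)
    _, prob_null, _, *_ = _prepare(data, spec, null_terms)

    fit_full = prob_full.fit(ylog, reml=False)
    fit_null = prob_null.fit(ylog, reml=False)
    lrt_obs = max(0.0, 2.0 * (fit_full["loglik"] - fit_null["loglik"]))

    ystar = _simulate_responses(prob_null, fit_null, n_boot, rng)
    lrt_star = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        f1 = prob_full.fit(ystar[b], reml=False, start=fit_full["s"])
        f0 = prob_null.fit(ystar[b], reml=False, start=fit_null["s"])
        if not (f1["converged"] and f0["converged"]):
            failures += 1
            lrt_star[b] = np.nan
            continue
        lrt_star[b] = max(0.0, 2.0 * (f1["loglik"] - f0["loglik"]))
    if failures > 0.05 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed to converge")
    ok = ~np.isnan(lrt_star)
    n_used = int(ok.sum())
    p = (1.0 + float((lrt_star[ok] >= lrt_obs - 1e-10).sum())) / (n_used + 1.0)
    df_diff = prob_full.p - prob_null.p
    return {
        "term": term,
        "lrt": lrt_obs,
        "df": df_diff,
        "p_value": p,
        "p_chi2": float(stats.chi2.sf(lrt_obs, df_diff)),
        "n_boot_used": n_used,
        "n_failures": failures,
    }


def pb_confint(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    contrast: str | np.ndarray = "night_vs_day",
    n_boot: int | None = None,
    seed: int | None = None,
    method: str = "REML",
) -> ContrastResult:
    """Percentile parametric-bootstrap CI for a cell-mean contrast, factor scale.

    Simulates from the fitted full model, refits each replicate, and takes
    percentile quantiles of ``exp(contrast)``.
    """
    n_boot = int(n_boot if n_boot is not None else spec.n_boot)
    seed = seed if seed is not None else spec.seed
    rng = np.random.default_rng(seed)

    result = fit_lmm(data, spec, method=method)
    problem: _LMMProblem = result._state["problem"]
    fit = result._state["fit"]
    name, est = contrast_estimate(result, contrast)
    w = _contrast_weights(contrast) if isinstance(contrast, str) else np.asarray(contrast, float)

    # map cell-mean weights onto this design's coefficient order
    beta_to_cells = _beta_to_cells_matrix(result)
    wbeta = beta_to_cells.T @ w

    ystar = _simulate_responses(problem, fit, n_boot, rng)
    vals = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        fb = problem.fit(ystar[b], reml=(method == "REML"), start=fit["s"])
        if not fb["converged"]:
            failures += 1
            vals[b] = np.nan
            continue
        vals[b] = wbeta @ fb["beta"]
    if failures > 0.05 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed to converge")
    vals = vals[~np.isnan(vals)]
    alpha = 1.0 - spec.ci_level
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ContrastResult(
        name=name,
        log_estimate=est,
        factor=float(np.exp(est)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        n_boot_used=int(vals.size),
    )


def _beta_to_cells_matrix(result: FitResult) -> np.ndarray:
    """Matrix M with cell_means = M @ beta for the fit's coding."""
    k = len(result.beta)
    M = np.zeros((6, k))
    basis = pd.Series(np.zeros(k), index=result.beta.index)
    for j in range(k):
        basis.iloc[:] = 0.0
        basis.iloc[j] = 1.0
        for i, (c, w) in enumerate(CELLS):
            M[i, j] = _cell_mean_from_beta(basis, result.coding, c, w)
    return M


# ---------------------------------------------------------------------------
# sklearn-style front end


class CrossedLMM(BaseEstimator):
    """Crossed random-intercepts Gaussian LMM as a scikit-learn estimator.

    Fits ``log(y + offset)`` with a condition x window fixed-cell structure
    and random intercepts for horse and calendar date.

    Parameters
    ----------
    offset : float or "auto"
        Constant c in log(y + c); "auto" derives half the smallest observable
        nonzero outcome from the data (0 when all outcomes are positive).
    method : {"REML", "ML"}
    coding : {"cell_means", "treatment"}

    Attributes
    ----------
    beta_ : pd.Series of fixed-effect coefficients (log scale)
    sigma2_horse_, sigma2_date_, sigma2_resid_ : variance components
    loglik_ : profiled (restricted) log-likelihood at the optimum
    converged_ : bool
    result_ : the underlying :class:`FitResult`
    """

    def __init__(self, offset: float | str = "auto", method: str = "REML", coding: str = "cell_means"):
        self.offset = offset
        self.method = method
        self.coding = coding

    def fit(self, X: pd.DataFrame, y=None, outcome: str = "lying_h_per_h") -> "CrossedLMM":
        """Fit from a metrics table ``X``; ``y`` optionally overrides the outcome column."""
        data = X.copy()
        if y is not None:
            outcome = "_outcome"
            data[outcome] = np.asarray(y, dtype=float)
        spec = ModelSpec(outcome=outcome, offset=self.offset, coding=self.coding)
        self.result_ = fit_lmm(data, spec, method=self.method)
        self.beta_ = self.result_.beta
        self.sigma2_horse_ = self.result_.sigma2_horse
        self.sigma2_date_ = self.result_.sigma2_date
        self.sigma2_resid_ = self.result_.sigma2_resid
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.offset_ = self.result_.offset
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction of the outcome on its original scale."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        cm = self.result_.cell_means()
        mu = np.array([cm.loc[c, w] for c, w in zip(X["condition"], X["window"])])
        return np.exp(mu) - self.offset_

    def contrasts(self) -> list[ContrastResult]:
        return marginal_condition_contrasts(self.result_)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Log-likelihood of a refit on X (sklearn model-selection hook)."""
        clone = CrossedLMM(**self.get_params()).fit(X, y)
        return clone.loglik_
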