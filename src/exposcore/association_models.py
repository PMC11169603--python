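"""Regression models of depression severity: exposome-only, genome-only,
additive (G+E) and multiplicative-interaction (G×E) fits, bootstrap
backward-AIC stability selection, Nagelkerke pseudo R², FDR correction,
leave-one-out sensitivity and stratified refits.

Binary outcomes (the HADS-D threshold indicators) are fitted with logistic
regression; the 4-level severity outcome with a multinomial logit using the
no-depression category as the reference.  Effect sizes are reported as odds
ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

LEVEL_NAMES = {0: "none", 1: "mild", 2: "moderate", 3: "severe"}
Z975 = norm.ppf(0.975)

__all__ = ["ModelSpec", "FitResult", "SelectionResult", "build_design",
           "fit_binary", "fit_multinomial", "fit_gxe", "nagelkerke_r2",
           "bootstrap_backward_select", "sensitivity_leave_one_out",
           "fdr_adjust", "stratified_fit"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``outcome`` is a binary column (``dep_mild``/``dep_moderate``/
    ``dep_severe``) or ``severity4`` for the multinomial model.
    ``predictors`` are the risk-score terms of interest; ``covariates`` are
    adjustment terms (``education`` expands into two indicator contrasts of
    the 3-level ordered factor).  ``interactions`` lists (a, b) product
    terms; both main effects must be declared.  ``forced_in`` terms are
    exempt from elimination; by default all covariates are forced in.
    """

    outcome: str
    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = ("age", "sex", "education")
    interactions: tuple[tuple[str, str], ...] = ()
    forced_in: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a == b:
                raise ValueError(f"interaction of a term with itself: {a}")
            for t in (a, b):
                if t not in self.predictors and t not in self.covariates:
                    raise ValueError(f"interaction references undeclared main effect {t!r}")

    @property
    def forced(self) -> tuple[str, ...]:
        return self.covariates if self.forced_in is None else self.forced_in


def _expand_terms(data: pd.DataFrame, terms) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if t == "education":
            edu = data["education"].to_numpy()
            cols["edu_secondary"] = (edu == 1).astype(float)
            cols["edu_graduate"] = (edu == 2).astype(float)
        else:
            cols[t] = data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Build (y, X) for a spec; X includes a constant and interaction
    columns named ``a:b``.  Raises on a rank-deficient design, naming the
    offending columns."""
    X = _expand_terms(data, tuple(spec.predictors) + tuple(spec.covariates))
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # pivoted QR localises the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        offending = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")
    y = data[spec.outcome].to_numpy()
    return y, X


@dataclass
class FitResult:
    """Tidy regression result: one row per term (and per outcome level for
    multinomial fits) with OR = exp(coef) and Wald 95% CI, plus model-level
    log-likelihood, AIC, Nagelkerke R² and n."""

    table: pd.DataFrame
    llf: float
    llnull: float
    aic: float
    n: int
    nagelkerke: float
    warnings_: list[str] = field(default_factory=list)

    def term(self, term: str, level: str | None = None) -> pd.Series:
        t = self.table[self.table["term"] == term]
        if level is not None:
            t = t[t["level"] == level]
        if len(t) != 1:
            raise KeyError(f"term {term!r} (level={level!r}) not uniquely present")
        return t.iloc[0]

    def with_fdr(self, q) -> "FitResult":
        out = self.table.copy()
        out["q"] = q
        return replace(self, table=out)


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo R²: the Cox–Snell R² rescaled by its maximum,
    [1 - exp((2/n)(LL0 - LL1))] / [1 - exp((2/n) LL0)]."""
    if llf < llnull - 1e-6:
        raise ValueError(f"fit log-likelihood {llf} below null {llnull}: fitting bug")
    cox_snell = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    max_cs = 1.0 - np.exp((2.0 / n) * llnull)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def _wald_rows(terms, level, params, bses, pvals):
    rows = []
    for t, b, se, p in zip(terms, params, bses, pvals):
        rows.append({"term": t, "level": level, "coef": float(b), "se": float(se),
                     "or": float(np.exp(b)),
                     "ci_low": float(np.exp(b - Z975 * se)),
                     "ci_high": float(np.exp(b + Z975 * se)),
                     "p": float(p)})
    return rows


def fit_binary(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood logistic regression with Wald CIs and p-values.

    Quasi-separation is flagged as a warning on the result rather than
    raised, matching the exploratory use of these fits."""
    y, X = build_design(data, spec)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"outcome {spec.outcome!r} must have both classes, got {classes}")
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except PerfectSeparationError:
            warns.append("quasi-separation: falling back to regularized fit")
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                warns.append("quasi-separation detected; coefficients unstable")
    null = sm.Logit(y, X[["const"]]).fit(disp=0)
    table = pd.DataFrame(_wald_rows(X.columns, spec.outcome, res.params, res.bse, res.pvalues))
    r2 = nagelkerke_r2(float(res.llf), float(null.llf), len(y))
    return FitResult(table, float(res.llf), float(null.llf),
                     float(2 * X.shape[1] - 2 * res.llf), len(y), r2, warns)


def fit_multinomial(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Multinomial logit over the 4-level severity outcome with the
    no-depression category (code 0) as reference; one coefficient block per
    non-reference level."""
    y, X = build_design(data, spec)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("need at least 2 outcome categories")
    warns: list[str] = []
    if len(present) < 4:
        missing = [LEVEL_NAMES[k] for k in LEVEL_NAMES if k not in present]
        warns.append(f"empty outcome categories dropped: {missing}")
    # recode to consecutive integers so the reference is the lowest present
    recode = {v: i for i, v in enumerate(present)}
    yc = np.vectorize(recode.get)(y)
    res = sm.MNLogit(yc, X).fit(disp=0, maxiter=500, method="newton")
    null = sm.MNLogit(yc, X[["const"]]).fit(disp=0, maxiter=500, method="newton")
    rows = []
    params, bses, pvals = np.asarray(res.params), np.asarray(res.bse), np.asarray(res.pvalues)
    for j in range(params.shape[1]):
        level = LEVEL_NAMES.get(int(present[j + 1]), str(present[j + 1]))
        rows += _wald_rows(X.columns, level, params[:, j], bses[:, j], pvals[:, j])
    k = params.size
    r2 = nagelkerke_r2(float(res.llf), float(null.llf), len(y))
    return FitResult(pd.DataFrame(rows), float(res.llf), float(null.llf),
                     float(2 * k - 2 * res.llf), len(y), r2, warns)


def fit_gxe(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Multiplicative gene–environment interaction model: main effects plus
    the declared (PERS, PRS) product term(s)."""
    if not spec.interactions:
        raise ValueError("G×E spec must declare at least one interaction")
    for a, b in spec.interactions:
        if a not in spec.predictors or b not in spec.predictors:
            raise ValueError(f"both main effects ({a}, {b}) must be included as predictors")
    if spec.outcome == "severity4":
        return fit_multinomial(data, spec)
    return fit_binary(data, spec)


# ---------------------------------------------------------------------------
# Bootstrap backward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Bootstrap retention frequencies of candidate terms and the >= threshold
    retained set."""

    frequency: pd.Series
    threshold: float
    B: int
    seed: int
    redrawn: int = 0

    @property
    def retained(self) -> list[str]:
        return self.frequency[self.frequency >= self.threshold].index.tolist()


def _aic_fit(y, X, multinomial: bool) -> float:
    if multinomial:
        res = sm.MNLogit(y, X).fit(disp=0, maxiter=200, method="newton")
        k = np.asarray(res.params).size
    else:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        k = X.shape[1]
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("fit did not converge")
    return float(2 * k - 2 * res.llf)


def _backward_eliminate(y, X: pd.DataFrame, candidates: list[str], multinomial: bool) -> list[str]:
    """Drop, one at a time, the candidate whose removal most decreases AIC,
    until no removal decreases it.  Returns surviving candidates."""
    current = list(X.columns)
    surviving = list(candidates)
    aic = _aic_fit(y, X[current], multinomial)
    while surviving:
        best_term, best_aic = None, aic
        for t in surviving:
            cols = [c for c in current if c != t]
            a = _aic_fit(y, X[cols], multinomial)
            if a < best_aic:
                best_term, best_aic = t, a
        if best_term is None:
            break
        current.remove(best_term)
        surviving.remove(best_term)
        aic = best_aic
    return surviving


def bootstrap_backward_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    B: int = 1000,
    retain_threshold: float = 0.6,
    seed: int = 0,
    max_redraws: int = 100,
) -> SelectionResult:
    """Stability selection: backward elimination by AIC on each of ``B``
    bootstrap resamples (with replacement, size n); a term's retention
    frequency is the fraction of resamples in which it survives.

    Forced-in terms (by default the covariates) are never eliminated.
    Non-converging bootstrap fits are redrawn, up to ``max_redraws`` in
    total.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    multinomial = spec.outcome == "severity4"
    y, X = build_design(data, spec)
    forced_cols = set(_expand_terms(data.iloc[:2], spec.forced).columns) | {"const"}
    candidates = [c for c in X.columns if c not in forced_cols]
    if not candidates:
        raise ValueError("no candidate terms to select over")
    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in candidates}
    redrawn = 0
    done = 0
    while done < B:
        idx = rng.integers(0, len(y), size=len(y))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                survived = _backward_eliminate(y[idx], X.iloc[idx].reset_index(drop=True),
                                               candidates, multinomial)
        except (RuntimeError, PerfectSeparationError, np.linalg.LinAlgError):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError(f"exceeded {max_redraws} bootstrap redraws")
            continue
        for t in survived:
            counts[t] += 1
        done += 1
    freq = pd.Series({c: counts[c] / B for c in candidates}, name="retention_frequency")
    return SelectionResult(freq, retain_threshold, B, seed, redrawn)


# ---------------------------------------------------------------------------
# Sensitivity analysis and utilities
# ---------------------------------------------------------------------------

def sensitivity_leave_one_out(
    data: pd.DataFrame,
    components: list[str],
    spec: ModelSpec,
    env_term: str = "pers_env",
    level: str = "moderate",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-out sensitivity of the G×E interaction to the composition of
    the environment-domain score.

    For each component, the domain score is recomputed without it, the G×E
    model refitted, and the interaction OR/CI/p at ``level`` reported;
    ``crosses_alpha`` flags components whose omission moves the interaction
    p-value across ``alpha`` relative to the full model.
    """
    if len(components) < 2:
        raise ValueError("need at least 2 domain components")
    inter = next(i for i in spec.interactions if env_term in i)
    iname = f"{inter[0]}:{inter[1]}"
    lvl = level if spec.outcome == "severity4" else spec.outcome

    full = fit_gxe(data, spec)
    p_full = float(full.term(iname, lvl)["p"])

    rows = []
    for comp in components:
        d = data.copy()
        d[env_term] = data[components].sum(axis=1) - data[comp]
        fit = fit_gxe(d, spec)
        row = fit.term(iname, lvl)
        rows.append({"omitted": comp, "or": row["or"], "ci_low": row["ci_low"],
                     "ci_high": row["ci_high"], "p": row["p"],
                     "crosses_alpha": (row["p"] < alpha) != (p_full < alpha)})
    return pd.DataFrame(rows)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stratified_fit(data: pd.DataFrame, spec: ModelSpec,
                   stratifier: str = "prepandemic_positive") -> dict:
    """Fit the identical model separately within each stratum of
    ``stratifier``; results keyed by stratum value."""
    out = {}
    values = sorted(pd.unique(data[stratifier]))
    for v in values:
        sub = data[data[stratifier] == v]
        if len(sub) == 0:
            raise ValueError(f"stratum {stratifier}={v} is empty")
        if spec.outcome == "severity4":
            out[v] = fit_multinomial(sub, spec)
        else:
            out[v] = fit_binary(sub, spec)
    if len(out) < 2:
        raise ValueError(f"stratifier {stratifier!r} has a single stratum: {values}")
    return out
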