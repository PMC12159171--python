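"""Cohort statistics: group comparisons, correlation battery, regressions.

The battery mirrors the analysis plan of a two-group (patients vs controls)
sleep-imaging study: Mann-Whitney U tests for continuous group differences,
an exact test for the sex split, Spearman rank correlations of the
ALPS-index against polysomnographic covariates within each group with
Bonferroni familywise correction, a pooled OLS model with an AHI-by-group
interaction term to test whether the ALPS-AHI relationship differs between
groups, per-group post-hoc regressions, and a comorbidity-adjusted model in
the patient group. Coefficients are reported both unstandardized (B) and
standardized (Beta = B * sd(x) / sd(y)).

Binary codings used throughout (recorded in every output): group PD=1,
control=0; sex male=1, female=0.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import ConfigurationError, RegressionError

#: The default correlation-battery covariates (the clinical report's 14).
CORRELATION_VARIABLES = (
    "age", "bmi", "tst", "sl", "se", "wake", "n1", "n2", "n3", "r",
    "ahi", "odi", "plmi", "arousal_index",
)

#: Continuous variables compared between groups in the demographics table.
COMPARISON_VARIABLES = (
    "age", "bmi", "alps", "tst", "sl", "se", "wake", "n1", "n2", "n3", "r",
    "ahi", "odi", "plmi", "arousal_index",
)

CODING = {"group": {"PD": 1, "control": 0}, "sex": {"M": 1, "F": 0}}


@dataclass
class ComparisonResult:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # 'exact' | 'asymptotic' | 'exact-2x2' | 'degenerate'
    mc_p: float | None = None
    mc_interval: tuple | None = None
    bonferroni_significant: bool | None = None


@dataclass
class CorrelationResult:
    variable: str
    target: str
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    group: str | None = None
    undefined: bool = False
    bonferroni_significant: bool | None = None


@dataclass
class RegressionTable:
    """OLS results shaped like a clinical regression table."""

    dependent: str
    rows: list  # dicts: term, B, SE, Beta, t, p
    n: int
    group_scope: str
    coding: dict = dc_field(default_factory=lambda: dict(CODING))
    r_squared: float = float("nan")
    dropped_terms: list = dc_field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["term", "B", "SE", "Beta", "t", "p"])

    def coefficient(self, term: str) -> dict:
        for row in self.rows:
            if row["term"] == term:
                return row
        raise KeyError(term)


# --------------------------------------------------------------------------
# univariate tests
# --------------------------------------------------------------------------

def mann_whitney(a, b, variable: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when n1+n2 <= 12 and the pooled sample
    is tie-free; otherwise the normal approximation with tie and continuity
    corrections. All-identical pooled data yields p=1 (degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 1 or b.size < 1:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return ComparisonResult(variable, a.mean(), a.std(ddof=1) if a.size > 1 else 0.0,
                                b.mean(), b.std(ddof=1) if b.size > 1 else 0.0,
                                u_statistic=a.size * b.size / 2.0, p_value=1.0,
                                n_a=a.size, n_b=b.size, method="degenerate")
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return ComparisonResult(
        variable,
        float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0,
        float(b.mean()), float(b.std(ddof=1)) if b.size > 1 else 0.0,
        u_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size), n_b=int(b.size), method=method)


def spearman_ci(x, y, alpha: float = 0.05, variable: str = "",
                target: str = "", group: str | None = None,
                p_method: str = "fieller") -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Pairwise deletion of non-finite pairs; rho via ranked Pearson with
    average ranks for ties; CI = tanh(atanh(rho) +- z/sqrt(n-3)). The
    default p-value uses the Fieller-corrected Fisher z statistic
    z = atanh(rho)*sqrt((n-3)/1.06), whose type-I error stays at or below
    nominal in the far tails at moderate n — where the classical
    t approximation t = rho*sqrt((n-2)/(1-rho^2)) (``p_method='t'``) is
    slightly anti-conservative and can push Bonferroni familywise error
    past its bound. Zero variance in either ranked variable yields an
    undefined, flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ConfigurationError(f"need n >= 4 finite pairs, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(variable, target, float("nan"), float("nan"),
                                 float("nan"), float("nan"), n, group,
                                 undefined=True)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rho, p_t = sps.spearmanr(x, y)
    if p_method == "t":
        p = p_t
    elif p_method == "fieller":
        with np.errstate(divide="ignore"):
            z_stat = np.arctanh(np.clip(rho, -1, 1)) * np.sqrt((n - 3) / 1.06)
        p = float(2 * sps.norm.sf(abs(z_stat)))
    else:
        raise ConfigurationError(f"unknown p_method {p_method!r}")
    z_crit = sps.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(rho)
        half = z_crit / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(variable, target, float(rho), float(p),
                             float(lo), float(hi), n, group)


def bonferroni_flags(p_values, m: int | None = None,
                     alpha: float = 0.05) -> list[bool]:
    """Familywise significance flags: p <= alpha / m."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m <= 0:
        raise ConfigurationError("Bonferroni family size m must be > 0")
    cut = alpha / m
    return [bool(np.isfinite(p) and p <= cut) for p in p_values]


def monte_carlo_p_interval(statistic, a, b, n_permutations: int = 10000,
                           seed: int = 0, level: float = 0.99,
                           alternative: str = "two-sided"):
    """Permutation p-value with add-one correction and a Clopper-Pearson
    interval for the exceedance proportion.

    ``statistic(a, b)`` is recomputed under random reassignments of the
    pooled sample to the two groups. Two-sided exceedance compares absolute
    statistic values. Returns (p, (low, high)).
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = statistic(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        t = statistic(perm[:n_a], perm[n_a:])
        if alternative == "two-sided":
            exceed = abs(t) >= abs(obs) - 1e-12
        elif alternative == "greater":
            exceed = t >= obs - 1e-12
        else:
            exceed = t <= obs + 1e-12
        k += bool(exceed)
    p = (k + 1) / (n_permutations + 1)
    tail = (1 - level) / 2
    lo = sps.beta.ppf(tail, k, n_permutations - k + 1) if k > 0 else 0.0
    hi = (sps.beta.ppf(1 - tail, k + 1, n_permutations - k)
          if k < n_permutations else 1.0)
    return float(p), (float(lo), float(hi))


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

def _encode(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric copy with recorded binary codings for group and sex."""
    df = table.copy()
    if "group" in df and df["group"].dtype == object:
        df["group"] = df["group"].map(CODING["group"])
    if "sex" in df and df["sex"].dtype == object:
        df["sex"] = df["sex"].map(CODING["sex"])
    return df


def _ols_table(y: pd.Series, X: pd.DataFrame, dependent: str,
               group_scope: str, dropped: list) -> RegressionTable:
    n = len(y)
    if n <= X.shape[1] + 2:
        raise RegressionError(
            f"n={n} too small for {X.shape[1]} terms plus intercept")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = []
        for col in X.columns:
            sub = design.drop(columns=[col])
            if np.linalg.matrix_rank(sub.values) == rank:
                bad.append(col)
        raise RegressionError(f"singular design; collinear terms: {bad or 'unknown'}")
    fit = sm.OLS(y.values, design.values).fit()
    sd_y = float(np.std(y.values, ddof=1))
    rows = []
    names = ["(Constant)"] + list(X.columns)
    for j, term in enumerate(names):
        B = float(fit.params[j])
        se = float(fit.bse[j])
        if term == "(Constant)":
            beta = float("nan")
        else:
            sd_x = float(np.std(X[term].values, ddof=1))
            beta = B * sd_x / sd_y if sd_y > 0 else float("nan")
        rows.append({"term": term, "B": B, "SE": se, "Beta": beta,
                     "t": float(fit.tvalues[j]), "p": float(fit.pvalues[j])})
    return RegressionTable(dependent=dependent, rows=rows, n=n,
                           group_scope=group_scope,
                           r_squared=float(fit.rsquared),
                           dropped_terms=dropped)


def ols_with_interaction(table: pd.DataFrame, dependent: str = "alps",
                         terms=("ahi", "age", "sex", "se", "plmi", "group"),
                         interaction: tuple[str, str] = ("ahi", "group")
                         ) -> RegressionTable:
    """Pooled OLS with an exposure-by-group interaction column.

    The interaction column is exposure * group_indicator (PD=1), so its
    coefficient is the patient-group excess slope of the exposure.
    """
    df = _encode(table)
    cols = list(terms)
    for c in (dependent, *cols):
        if c not in df:
            raise ConfigurationError(f"column {c!r} missing from cohort table")
    use = df[[dependent, *cols]].dropna()
    X = use[cols].astype(float).copy()
    if interaction is not None:
        e, gcol = interaction
        name = f"{e}_x_{gcol}"
        X[name] = use[e].astype(float) * use[gcol].astype(float)
    return _ols_table(use[dependent].astype(float), X, dependent,
                      group_scope="pooled", dropped=[])


def run_group_comparisons(table: pd.DataFrame,
                          variables=COMPARISON_VARIABLES,
                          alpha: float = 0.05, m: int | None = None,
                          mc_permutations: int = 0, seed: int = 0
                          ) -> list[ComparisonResult]:
    """Demographics-table battery: Mann-Whitney per continuous variable,
    exact 2x2 test for the sex split, Bonferroni flags over the continuous
    family (m defaults to the number of continuous comparisons)."""
    groups = table["group"].unique()
    if len(groups) != 2:
        raise ConfigurationError("group comparisons need exactly two groups")
    g1 = table[table["group"] == "PD"]
    g2 = table[table["group"] != "PD"]
    results = []
    for var in variables:
        if var not in table:
            continue
        a = g1[var].to_numpy(dtype=float)
        b = g2[var].to_numpy(dtype=float)
        res = mann_whitney(a, b, variable=var)
        if mc_permutations:
            res.mc_p, res.mc_interval = monte_carlo_p_interval(
                lambda x, y: np.nanmean(x) - np.nanmean(y), a, b,
                n_permutations=mc_permutations, seed=seed)
        results.append(res)
    flags = bonferroni_flags([r.p_value for r in results],
                             m=m if m is not None else len(results),
                             alpha=alpha)
    for r, f in zip(results, flags):
        r.bonferroni_significant = f
    if "sex" in table:
        tab = np.array([
            [(g1["sex"] == "F").sum(), (g1["sex"] == "M").sum()],
            [(g2["sex"] == "F").sum(), (g2["sex"] == "M").sum()],
        ])
        _, p = sps.fisher_exact(tab, alternative="two-sided")
        results.append(ComparisonResult(
            "sex", float(tab[0, 1] / tab[0].sum()), float("nan"),
            float(tab[1, 1] / tab[1].sum()), float("nan"),
            u_statistic=float("nan"), p_value=float(p),
            n_a=int(tab[0].sum()), n_b=int(tab[1].sum()),
            method="exact-2x2", bonferroni_significant=None))
    return results


def run_correlation_battery(table: pd.DataFrame, target: str = "alps",
                            variables=CORRELATION_VARIABLES,
                            per_group: bool = True, m: int | None = None,
                            alpha: float = 0.05) -> list[CorrelationResult]:
    """Spearman correlations of the target against each covariate, within
    each group, Bonferroni-corrected with family size m per group (default:
    the number of covariates)."""
    varlist = [v for v in variables if v in table.columns]
    fam = m if m is not None else len(varlist)
    results: list[CorrelationResult] = []
    groups = table["group"].unique() if per_group else [None]
    for grp in groups:
        sub = table if grp is None else table[table["group"] == grp]
        block = []
        for var in varlist:
            block.append(spearman_ci(sub[var], sub[target], alpha=alpha,
                                     variable=var, target=target,
                                     group=None if grp is None else str(grp)))
        flags = bonferroni_flags([r.p_value for r in block], m=fam, alpha=alpha)
        for r, f in zip(block, flags):
            r.bonferroni_significant = f and not r.undefined
        results.extend(block)
    return results


def run_posthoc_regressions(table: pd.DataFrame, dependent: str = "alps",
                            terms=("ahi", "age", "sex", "se", "plmi")
                            ) -> dict[str, RegressionTable]:
    """Per-group OLS of the dependent on the covariates (no interaction)."""
    out = {}
    for grp in table["group"].unique():
        sub = _encode(table[table["group"] == grp])
        use = sub[[dependent, *terms]].dropna()
        X = use[list(terms)].astype(float)
        out[str(grp)] = _ols_table(use[dependent].astype(float), X, dependent,
                                   group_scope=str(grp), dropped=[])
    return out


def run_confounder_adjustment(table: pd.DataFrame, dependent: str = "alps",
                              exposure: str = "ahi",
                              confounders=("rbd", "rls", "plms")
                              ) -> RegressionTable:
    """Comorbidity-adjusted exposure model in the patient subset.

    Zero-variance confounders (e.g. a flag nobody carries) are dropped and
    listed in ``dropped_terms``, so the exposure coefficient then matches
    the unadjusted simple regression.
    """
    sub = table[table["group"] == "PD"] if "group" in table else table
    df = _encode(sub)
    cols = [exposure]
    dropped = []
    for c in confounders:
        if c not in df:
            dropped.append(c)
            continue
        if df[c].astype(float).std(ddof=0) == 0:
            dropped.append(c)
        else:
            cols.append(c)
    use = df[[dependent, *cols]].dropna()
    X = use[cols].astype(float)
    return _ols_table(use[dependent].astype(float), X, dependent,
                      group_scope="PD", dropped=dropped)
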