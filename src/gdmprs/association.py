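"""Univariate screening, multivariate logistic regression, quintile
association, and PRS–glucose correlation.

The multivariate model is fitted by Newton–Raphson IRLS with Wald standard
errors; odds ratios are exp(beta) with 95% CIs exp(beta +/- 1.96 SE), the
style of standard epidemiological software output. The PRS enters the model
on its RAW score scale by default: with a raw-score SD near 0.08 a per-unit
OR of ~20 corresponds to a per-SD OR of only ~1.27, which is the scale on
which headline PRS odds ratios of this kind are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr
from scipy.stats import chi2_contingency, fisher_exact, pearsonr, ttest_ind

Z975 = 1.959963984540054  # Phi^{-1}(0.975)

#: Expansion of model terms into design columns, in fixed documented order.
TERM_COLUMNS: dict[str, list[str]] = {
    "pbmi": ["pbmi"],
    "age": ["age"],
    "employment": ["employment"],
    "smoking": ["smoking"],
    "alcohol": ["alcohol"],
    "decoration": ["decoration"],
    "gravidity": ["gravidity_2", "gravidity_ge3"],
    "parity": ["parity_ge2"],
    "prs": ["prs"],
}

#: The traditional-risk-factor model terms.
TRADITIONAL_TERMS = ["pbmi", "age", "employment", "gravidity", "parity"]

DEFAULT_CONTINUOUS = ("age", "pbmi")
DEFAULT_CATEGORICAL = (
    "gravidity",
    "parity",
    "decoration",
    "smoking",
    "physical_activity",
    "alcohol",
    "employment",
    "education",
    "economic",
)


class DesignError(ValueError):
    """Raised for rank-deficient or malformed design matrices."""


# --------------------------------------------------------------------------
# univariate screening


def _screen_categorical(values: np.ndarray, y: np.ndarray) -> tuple[str, float, float]:
    table = pd.crosstab(y, values).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return "none", float("nan"), float("nan")
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = fisher_exact(table)
        return "fisher", float("nan"), float(p)
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return "chi2", float(stat), float(p)


def univariate_screen(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen covariates against GDM status one at a time.

    Continuous variables use the classic equal-variance two-sample t-test
    (Welch available via :func:`scipy.stats.ttest_ind` directly); categorical
    variables use the Pearson chi-square without continuity correction,
    switching to Fisher's exact test for 2x2 tables with any expected cell
    count below 5. A constant variable is flagged untestable (test "none",
    p NaN) rather than raising. ``selected`` is ``p < alpha``.
    """
    y = cohort["gdm"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present for screening")
    rows = []
    for name in continuous:
        x = cohort[name].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append((name, "none", float("nan"), float("nan")))
            continue
        stat, p = ttest_ind(x[y == 1], x[y == 0], equal_var=True)
        rows.append((name, "t", float(stat), float(p)))
    for name in categorical:
        test, stat, p = _screen_categorical(cohort[name].to_numpy(), y)
        rows.append((name, test, stat, p))
    out = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
    out["selected"] = out["p"] < alpha
    return out


# --------------------------------------------------------------------------
# design construction


def build_design(
    cohort: pd.DataFrame,
    terms: list[str] = TRADITIONAL_TERMS,
    prs: pd.DataFrame | np.ndarray | None = None,
    prs_scale: str = "raw",
) -> pd.DataFrame:
    """Design matrix with a leading intercept column ``const``.

    ``gravidity`` expands into indicators for 2 and >=3 pregnancies (1 is the
    reference); ``parity`` into an indicator for >=2 births. The PRS column
    uses the raw score by default (``prs_scale="z"`` switches to the
    standardized score).
    """
    X = pd.DataFrame({"const": np.ones(len(cohort))})
    for term in terms:
        if term == "prs":
            if prs is None:
                raise DesignError("model includes 'prs' but no scores were given")
            if isinstance(prs, pd.DataFrame):
                col = "raw_score" if prs_scale == "raw" else "z_score"
                values = prs[col].to_numpy(float)
            else:
                values = np.asarray(prs, float)
            X["prs"] = values
        elif term == "gravidity":
            X["gravidity_2"] = (cohort["gravidity"].to_numpy() == 2).astype(float)
            X["gravidity_ge3"] = (cohort["gravidity"].to_numpy() == 3).astype(float)
        elif term == "parity":
            X["parity_ge2"] = (cohort["parity"].to_numpy() == 2).astype(float)
        elif term in cohort.columns:
            X[term] = cohort[term].to_numpy(float)
        else:
            raise DesignError(f"unknown model term {term!r}")
    return X


# --------------------------------------------------------------------------
# logistic regression by IRLS


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, Wald inference, diagnostics."""

    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    n_iter: int
    n_obs: int
    separation_suspected: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - Z975 * self.bse)
        hi = np.exp(self.params + Z975 * self.bse)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = (self.params / self.bse).to_numpy(float)
        return pd.Series(2.0 * ndtr(-np.abs(z)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "odds_ratio": self.odds_ratios,
                "ci_low": ci["ci_low"],
                "ci_high": ci["ci_high"],
                "p": self.pvalues,
            }
        )


def _log_likelihood(y: np.ndarray, lp: np.ndarray) -> float:
    # Numerically stable: -log(1+exp(-lp)) for y=1, -log(1+exp(lp)) for y=0.
    return float(-np.logaddexp(0.0, np.where(y == 1, -lp, lp)).sum())


def fit_logistic(
    design: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton–Raphson IRLS.

    Converges when the maximum absolute score (gradient) drops below
    ``score_tol`` or the relative log-likelihood change below ``ll_tol``.
    Rank-deficient designs raise :class:`DesignError` naming the collinear
    columns; quasi-separation (any |beta| > 15) sets
    ``separation_suspected`` instead of failing silently.
    """
    X = design.to_numpy(float)
    names = list(design.columns)
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        raise DesignError(
            f"design is rank deficient; collinear columns: "
            f"{[names[i] for i in np.flatnonzero(bad)]}"
        )

    beta = np.zeros(p)
    if "const" in names:
        beta[names.index("const")] = logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    ll = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, score)
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        if abs(ll_new - ll) < ll_tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    bse = np.sqrt(np.diag(cov))
    separation = bool(np.any(np.abs(beta) > 15))
    flags = ["separation_suspected"] if separation else []
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        llf=_log_likelihood(y, X @ beta),
        converged=converged,
        n_iter=it,
        n_obs=n,
        separation_suspected=separation,
        flags=flags,
    )


def predict_proba(fit: LogisticFit, design: pd.DataFrame) -> np.ndarray:
    """Predicted event probabilities for a design matrix."""
    return expit(design[fit.params.index].to_numpy(float) @ fit.params.to_numpy())


# --------------------------------------------------------------------------
# quintile association


def quintile_association(
    cohort: pd.DataFrame,
    prs: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """Odds ratios for GDM across PRS quintiles (Q1 = reference).

    Unadjusted: logistic regression on the four upper-quintile indicators.
    ``adjust=True`` adds the traditional risk factors. A quintile with an
    empty case or control cell gets an undefined (NaN) OR.
    """
    q = prs["quintile"].to_numpy(int)
    y = cohort["gdm"].to_numpy(int)
    counts = pd.DataFrame(
        {
            "quintile": np.arange(1, 6),
            "cases": [int(y[q == k].sum()) for k in range(1, 6)],
            "controls": [int((q == k).sum() - y[q == k].sum()) for k in range(1, 6)],
        }
    )
    X = pd.DataFrame({"const": np.ones(len(cohort))})
    for k in range(2, 6):
        X[f"q{k}"] = (q == k).astype(float)
    if adjust:
        X = pd.concat(
            [X, build_design(cohort, TRADITIONAL_TERMS).drop(columns="const")], axis=1
        )
    defined = (counts["cases"] > 0) & (counts["controls"] > 0)
    out = counts.copy()
    out[["odds_ratio", "ci_low", "ci_high", "p"]] = np.nan
    out.loc[out["quintile"] == 1, ["odds_ratio", "ci_low", "ci_high"]] = [1.0, 1.0, 1.0]
    if defined.all():
        fit = fit_logistic(X, y)
        s = fit.summary()
        for k in range(2, 6):
            out.loc[out["quintile"] == k, ["odds_ratio", "ci_low", "ci_high", "p"]] = (
                s.loc[f"q{k}", ["odds_ratio", "ci_low", "ci_high", "p"]].to_numpy()
            )
    else:
        # fall back to 2x2 cross-products vs Q1 where defined
        a0 = counts.loc[0, "cases"]
        b0 = counts.loc[0, "controls"]
        for k in range(2, 6):
            ak = counts.loc[k - 1, "cases"]
            bk = counts.loc[k - 1, "controls"]
            if min(ak, bk, a0, b0) > 0:
                out.loc[out["quintile"] == k, "odds_ratio"] = (ak * b0) / (bk * a0)
    return out


# --------------------------------------------------------------------------
# PRS–glucose correlation


def prs_glucose_correlation(
    prs: pd.DataFrame,
    cohort: pd.DataFrame,
    measures: tuple[str, ...] = ("fpg", "ogtt_1h", "ogtt_2h"),
) -> pd.DataFrame:
    """Pearson correlation (with two-sided t-test p) of PRS vs each glucose
    measure, pairwise-complete."""
    score = prs["raw_score"].to_numpy(float)
    rows = []
    for name in measures:
        g = cohort[name].to_numpy(float)
        ok = ~(np.isnan(score) | np.isnan(g))
        n = int(ok.sum())
        if n < 3 or np.ptp(g[ok]) == 0 or np.ptp(score[ok]) == 0:
            rows.append((name, float("nan"), float("nan"), n, True))
            continue
        r, p = pearsonr(score[ok], g[ok])
        rows.append((name, float(r), float(p), n, False))
    return pd.DataFrame(rows, columns=["measure", "r", "p", "n", "degenerate"])
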