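"""Incremental predictive value of adding PRS to a risk model.

Implements the comparison toolkit for nested risk models: ROC/AUC by the
Mann–Whitney construction with DeLong variance and paired DeLong tests,
integrated discrimination improvement (IDI), net reclassification improvement
(NRI, continuous by default) with its event/non-event decomposition,
subject-level stratified bootstrap CIs, and five-fold cross-validation in
which training folds are under-sampled to a 1:1 case:control ratio while
test folds keep their natural prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from gdmprs._rng import child_rng
from gdmprs.association import (
    TRADITIONAL_TERMS,
    build_design,
    fit_logistic,
    predict_proba,
)

Z975 = 1.959963984540054

#: The three model specifications compared in the headline analysis.
DEFAULT_MODEL_SPECS: dict[str, list[str]] = {
    "prs_only": ["prs"],
    "traditional": list(TRADITIONAL_TERMS),
    "traditional_plus_prs": list(TRADITIONAL_TERMS) + ["prs"],
}


# --------------------------------------------------------------------------
# ROC / AUC with DeLong inference


@dataclass
class RocCurve:
    """An ROC curve with its AUC, DeLong variance and Wald 95% CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    delong_var: float
    ci_low: float
    ci_high: float


def _check_binary(outcome: np.ndarray) -> np.ndarray:
    y = np.asarray(outcome, int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (per-case V10, per-control V01)."""
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = cases.size, controls.size
    tz = rankdata(np.concatenate([cases, controls]))
    tx = rankdata(cases)
    ty = rankdata(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def roc_auc(scores: np.ndarray, outcome: np.ndarray) -> RocCurve:
    """ROC curve and AUC (ties count 1/2) with DeLong variance.

    Points are generated at every unique score threshold (prediction positive
    when score >= threshold), bracketed by the (0,0) and (1,1) endpoints.
    """
    scores = np.asarray(scores, float)
    y = _check_binary(outcome)
    auc, v10, v01 = _delong_components(scores, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var = 0.0
    if m > 1 and n > 1:
        var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    se = np.sqrt(var)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[y == 0] >= t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
        delong_var=var,
        ci_low=float(max(0.0, auc - Z975 * se)),
        ci_high=float(min(1.0, auc + Z975 * se)),
    )


def compare_auc(
    scores_old: np.ndarray, scores_new: np.ndarray, outcome: np.ndarray
) -> dict:
    """Paired DeLong test for the AUC difference of two scores on one cohort.

    Returns a dict with both AUCs, their difference, the DeLong standard
    error of the difference, z and the two-sided normal p. Identical ranks
    give delta = 0 and p = 1.
    """
    s_old = np.asarray(scores_old, float)
    s_new = np.asarray(scores_new, float)
    if s_old.shape != s_new.shape:
        raise ValueError("paired scores must cover identical subjects")
    y = _check_binary(outcome)
    a_old, v10_o, v01_o = _delong_components(s_old, y)
    a_new, v10_n, v01_n = _delong_components(s_new, y)
    m, n = v10_o.size, v01_o.size
    var = 0.0
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10_o, v10_n]), ddof=1)
        s01 = np.cov(np.vstack([v01_o, v01_n]), ddof=1)
        var = float(
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
    delta = a_new - a_old
    if var <= 0:
        z = 0.0
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * ndtr(-abs(z)))
    return {
        "auc_old": a_old,
        "auc_new": a_new,
        "delta_auc": delta,
        "se": float(np.sqrt(max(var, 0.0))),
        "z": float(z),
        "p": p,
    }


# --------------------------------------------------------------------------
# IDI and NRI


@dataclass
class Estimate:
    """A point estimate with a percentile bootstrap CI and normal-approx p."""

    value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")


def _bootstrap_strata(
    y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(n_boot, n_case) and (n_boot, n_ctrl) resample index matrices."""
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    bc = case_idx[rng.integers(0, case_idx.size, (n_boot, case_idx.size))]
    bn = ctrl_idx[rng.integers(0, ctrl_idx.size, (n_boot, ctrl_idx.size))]
    return bc, bn


def _wrap(value: float, draws: np.ndarray | None) -> Estimate:
    if draws is None:
        return Estimate(value=float(value))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    sd = draws.std(ddof=1)
    p = float(2.0 * ndtr(-abs(value) / sd)) if sd > 0 else float(value == 0.0)
    return Estimate(value=float(value), ci_low=float(lo), ci_high=float(hi), p=p)


def idi(
    p_old: np.ndarray,
    p_new: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> Estimate:
    """Integrated discrimination improvement with stratified bootstrap CI.

    IDI = (mean p_new - mean p_old among events) - (the same among
    non-events); equivalently the change in discrimination slope. The CI is a
    subject-level percentile bootstrap stratified by outcome.
    """
    p_old = np.asarray(p_old, float)
    p_new = np.asarray(p_new, float)
    for p in (p_old, p_new):
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
    y = _check_binary(outcome)
    diff = p_new - p_old
    value = diff[y == 1].mean() - diff[y == 0].mean()
    if n_boot <= 0:
        return Estimate(value=float(value))
    rng = child_rng(seed, "bootstrap.idi")
    bc, bn = _bootstrap_strata(y, n_boot, rng)
    draws = diff[bc].mean(axis=1) - diff[bn].mean(axis=1)
    return _wrap(value, draws)


@dataclass
class NriResult:
    """Continuous or categorical NRI with its decomposition."""

    overall: Estimate
    event: Estimate
    nonevent: Estimate
    variant: str
    thresholds: tuple[float, ...] | None = None


def _direction(
    p_old: np.ndarray,
    p_new: np.ndarray,
    variant: str,
    thresholds: Sequence[float] | None,
) -> np.ndarray:
    """+1 where the new model moves risk up, -1 down, 0 unchanged."""
    if variant == "continuous":
        return np.sign(p_new - p_old)
    if thresholds is None or len(thresholds) == 0:
        raise ValueError("categorical NRI needs at least one threshold")
    t = np.asarray(sorted(thresholds), float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    return np.sign(np.digitize(p_new, t) - np.digitize(p_old, t)).astype(float)


def nri(
    p_old: np.ndarray,
    p_new: np.ndarray,
    outcome: np.ndarray,
    variant: str = "continuous",
    thresholds: Sequence[float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> NriResult:
    """Net reclassification improvement, decomposed by outcome class.

    NRI_event = P(up|event) - P(down|event); NRI_nonevent =
    P(down|nonevent) - P(up|nonevent); overall = their sum (an identity of
    the computation, not an approximation). The continuous variant counts any
    risk movement; the categorical variant counts movement across the given
    risk-category thresholds.
    """
    if variant not in ("continuous", "categorical"):
        raise ValueError(f"unknown NRI variant {variant!r}")
    p_old = np.asarray(p_old, float)
    p_new = np.asarray(p_new, float)
    y = _check_binary(outcome)
    d = _direction(p_old, p_new, variant, thresholds)
    ev = d[y == 1]
    ne = d[y == 0]
    nri_event = float((ev > 0).mean() - (ev < 0).mean())
    nri_nonevent = float((ne < 0).mean() - (ne > 0).mean())
    overall = nri_event + nri_nonevent
    if n_boot <= 0:
        return NriResult(
            overall=Estimate(overall),
            event=Estimate(nri_event),
            nonevent=Estimate(nri_nonevent),
            variant=variant,
            thresholds=None if thresholds is None else tuple(thresholds),
        )
    rng = child_rng(seed, "bootstrap.nri")
    bc, bn = _bootstrap_strata(y, n_boot, rng)
    up, down = (d > 0).astype(float), (d < 0).astype(float)
    ev_draws = up[bc].mean(axis=1) - down[bc].mean(axis=1)
    ne_draws = down[bn].mean(axis=1) - up[bn].mean(axis=1)
    return NriResult(
        overall=_wrap(overall, ev_draws + ne_draws),
        event=_wrap(nri_event, ev_draws),
        nonevent=_wrap(nri_nonevent, ne_draws),
        variant=variant,
        thresholds=None if thresholds is None else tuple(thresholds),
    )


# --------------------------------------------------------------------------
# incremental value of nested models (refit bootstrap)


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, beta0: np.ndarray, iters: int = 25,
    tol: float = 1e-8,
) -> np.ndarray:
    """Bare Newton–Raphson refit (warm-started); used inside bootstrap loops."""
    from scipy.special import expit as _expit

    beta = beta0.copy()
    for _ in range(iters):
        mu = _expit(X @ beta)
        g = X.T @ (y - mu)
        if np.abs(g).max() < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        beta += np.linalg.solve((X * w[:, None]).T @ X, g)
    return beta


def incremental_value(
    cohort: pd.DataFrame,
    prs: pd.DataFrame,
    terms_old: Sequence[str] | None = None,
    terms_new: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    nri_variant: str = "continuous",
    nri_thresholds: Sequence[float] | None = None,
) -> dict:
    """IDI and NRI of adding a predictor, with model-refit bootstrap CIs.

    Unlike :func:`idi`/:func:`nri` applied to fixed probability vectors, the
    bootstrap here resamples subjects (stratified by outcome) and REFITS both
    nested models in every draw, so the CIs carry the estimation uncertainty
    of the models themselves — without this the CIs undercover badly.
    """
    from scipy.special import expit as _expit

    if terms_old is None:
        terms_old = list(TRADITIONAL_TERMS)
    if terms_new is None:
        terms_new = list(TRADITIONAL_TERMS) + ["prs"]
    y = np.asarray(cohort["gdm"], int)
    X_old = build_design(cohort, list(terms_old), prs=prs).to_numpy(float)
    X_new = build_design(cohort, list(terms_new), prs=prs).to_numpy(float)
    fit_old = fit_logistic(build_design(cohort, list(terms_old), prs=prs), y)
    fit_new = fit_logistic(build_design(cohort, list(terms_new), prs=prs), y)
    b_old = fit_old.params.to_numpy()
    b_new = fit_new.params.to_numpy()
    p_old = _expit(X_old @ b_old)
    p_new = _expit(X_new @ b_new)
    idi_point = idi(p_old, p_new, y, n_boot=0).value
    nri_point = nri(
        p_old, p_new, y, variant=nri_variant, thresholds=nri_thresholds, n_boot=0
    )
    if n_boot <= 0:
        return {"idi": Estimate(idi_point), "nri": nri_point}

    rng = child_rng(seed, "bootstrap.incremental")
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    idi_draws = np.empty(n_boot)
    ev_draws = np.empty(n_boot)
    ne_draws = np.empty(n_boot)
    for b in range(n_boot):
        bc = case_idx[rng.integers(0, case_idx.size, case_idx.size)]
        bn = ctrl_idx[rng.integers(0, ctrl_idx.size, ctrl_idx.size)]
        take = np.concatenate([bc, bn])
        yb = np.r_[np.ones(bc.size), np.zeros(bn.size)]
        bo = _newton_logistic(X_old[take], yb, b_old)
        bnw = _newton_logistic(X_new[take], yb, b_new)
        po = _expit(X_old[take] @ bo)
        pn = _expit(X_new[take] @ bnw)
        d = _direction(po, pn, nri_variant, nri_thresholds)
        diff = pn - po
        idi_draws[b] = diff[: bc.size].mean() - diff[bc.size:].mean()
        ev = d[: bc.size]
        ne = d[bc.size:]
        ev_draws[b] = (ev > 0).mean() - (ev < 0).mean()
        ne_draws[b] = (ne < 0).mean() - (ne > 0).mean()
    return {
        "idi": _wrap(idi_point, idi_draws),
        "nri": NriResult(
            overall=_wrap(nri_point.overall.value, ev_draws + ne_draws),
            event=_wrap(nri_point.event.value, ev_draws),
            nonevent=_wrap(nri_point.nonevent.value, ne_draws),
            variant=nri_variant,
            thresholds=None if nri_thresholds is None else tuple(nri_thresholds),
        ),
    }


# --------------------------------------------------------------------------
# cross-validation with under-sampling


class FoldError(RuntimeError):
    """Raised when a CV fold cannot support model fitting."""


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """k outcome-stratified test folds (shuffled, sizes differing by <= 1)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, part in enumerate(np.array_split(idx, k)):
            folds[j].extend(part.tolist())
    return [np.sort(np.asarray(f)) for f in folds]


def undersample_controls(
    idx: np.ndarray, y: np.ndarray, rng: np.random.Generator, ratio: float = 1.0
) -> np.ndarray:
    """Drop random controls from ``idx`` down to ``ratio`` controls per case."""
    cases = idx[y[idx] == 1]
    ctrls = idx[y[idx] == 0]
    n_keep = min(ctrls.size, int(round(ratio * cases.size)))
    kept = rng.choice(ctrls, size=n_keep, replace=False)
    return np.sort(np.concatenate([cases, kept]))


@dataclass
class ComparisonReport:
    """Headline incremental-value report: full-data and CV-averaged metrics."""

    full: dict
    cv_folds: pd.DataFrame
    cv_means: dict
    n_boot: int
    seed: int
    nri_variant: str
    model_specs: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(x):
            if isinstance(x, Estimate):
                return {"value": x.value, "ci_low": x.ci_low, "ci_high": x.ci_high, "p": x.p}
            if isinstance(x, NriResult):
                return {
                    "overall": conv(x.overall),
                    "event": conv(x.event),
                    "nonevent": conv(x.nonevent),
                    "variant": x.variant,
                }
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            return x

        return {
            "full": conv(self.full),
            "cv_means": conv(self.cv_means),
            "cv_folds": self.cv_folds.to_dict(orient="records"),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "nri_variant": self.nri_variant,
            "model_specs": self.model_specs,
        }


def _model_probs(
    cohort: pd.DataFrame,
    prs: pd.DataFrame,
    terms: list[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    X = build_design(cohort, terms, prs=prs)
    y = cohort["gdm"].to_numpy(int)
    fit = fit_logistic(X.iloc[train_idx], y[train_idx])
    return predict_proba(fit, X.iloc[test_idx])


def cv_undersample_evaluate(
    cohort: pd.DataFrame,
    prs: pd.DataFrame,
    model_specs: Mapping[str, list[str]] | None = None,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
    nri_variant: str = "continuous",
    nri_thresholds: Sequence[float] | None = None,
    undersample_ratio: float = 1.0,
    paired: tuple[str, str] = ("traditional", "traditional_plus_prs"),
) -> ComparisonReport:
    """Evaluate nested risk models by k-fold CV with training under-sampling.

    Folds are stratified by outcome. Within each *training* fold only,
    controls are randomly under-sampled to ``undersample_ratio`` controls per
    case; models are fitted on the balanced training set and all metrics are
    computed on the untouched test fold (natural prevalence). The report also
    carries full-data estimates — models fitted once on the whole cohort,
    with bootstrap CIs for IDI/NRI and the DeLong test for the paired AUCs.
    """
    if model_specs is None:
        model_specs = DEFAULT_MODEL_SPECS
    if k < 2:
        raise ValueError("k must be >= 2")
    y = cohort["gdm"].to_numpy(int)
    if y.sum() < 5 * k:
        raise FoldError("need at least 5 cases per fold; reduce k")
    rng = child_rng(seed, "cv.folds")
    us_rng = child_rng(seed, "cv.undersample")
    folds = stratified_folds(y, k, rng)
    all_idx = np.arange(len(y))
    fold_rows = []
    for fold_no, test_idx in enumerate(folds, start=1):
        if len(np.unique(y[test_idx])) < 2:
            raise FoldError(f"fold {fold_no} has a single outcome class; reduce k")
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_idx = undersample_controls(train_idx, y, us_rng, undersample_ratio)
        row: dict = {"fold": fold_no, "n_test": len(test_idx), "n_train": len(train_idx)}
        probs: dict[str, np.ndarray] = {}
        for name, terms in model_specs.items():
            probs[name] = _model_probs(cohort, prs, terms, train_idx, test_idx)
            row[f"auc_{name}"] = roc_auc(probs[name], y[test_idx]).auc
        old, new = paired
        if old in probs and new in probs:
            cmp_res = compare_auc(probs[old], probs[new], y[test_idx])
            row["delta_auc"] = cmp_res["delta_auc"]
            row["delong_p"] = cmp_res["p"]
            row["idi"] = idi(probs[old], probs[new], y[test_idx], n_boot=0).value
            fold_nri = nri(
                probs[old], probs[new], y[test_idx],
                variant=nri_variant, thresholds=nri_thresholds, n_boot=0,
            )
            row["nri_overall"] = fold_nri.overall.value
            row["nri_event"] = fold_nri.event.value
            row["nri_nonevent"] = fold_nri.nonevent.value
        fold_rows.append(row)
    cv_folds = pd.DataFrame(fold_rows)
    cv_means = {
        c: float(cv_folds[c].mean()) for c in cv_folds.columns if c != "fold"
    }

    # full-data headline estimates
    full_probs: dict[str, np.ndarray] = {}
    full: dict = {}
    for name, terms in model_specs.items():
        X = build_design(cohort, terms, prs=prs)
        fit = fit_logistic(X, y)
        full_probs[name] = predict_proba(fit, X)
        curve = roc_auc(full_probs[name], y)
        full[f"auc_{name}"] = {
            "auc": curve.auc, "ci_low": curve.ci_low, "ci_high": curve.ci_high
        }
    old, new = paired
    if old in full_probs and new in full_probs:
        full["delong"] = compare_auc(full_probs[old], full_probs[new], y)
        inc = incremental_value(
            cohort, prs,
            terms_old=model_specs[old], terms_new=model_specs[new],
            n_boot=n_boot, seed=seed,
            nri_variant=nri_variant, nri_thresholds=nri_thresholds,
        )
        full["idi"] = inc["idi"]
        full["nri"] = inc["nri"]
    return ComparisonReport(
        full=full,
        cv_folds=cv_folds,
        cv_means=cv_means,
        n_boot=n_boot,
        seed=seed,
        nri_variant=nri_variant,
        model_specs={k_: list(v) for k_, v in model_specs.items()},
    )
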