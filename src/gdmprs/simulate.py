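"""Synthetic GDM case-control cohorts with known generative parameters.

The generator emulates the statistical structure a small-panel PRS analysis
assumes: covariates drawn from stated marginals, a weighted dosage score (or a
directly drawn Normal score), a logistic disease model at a calibrated
prevalence, OGTT glucose positively coupled to the linear predictor, and
low-pass-imputation noise on genotype dosages. Because every parameter is
known, downstream estimators can be tested for parameter recovery.

Two outcome modes exist:

``logistic``
    GDM ~ Bernoulli(expit(b0 + sum beta_j x_j)); the intercept b0 is
    root-found so the population prevalence matches ``prevalence_target``.
``ogtt_threshold``
    Glucose is generated first and GDM is *defined* by the diagnostic
    cutoffs (fasting >= 5.5, 1-h >= 10.0, 2-h >= 8.0 mmol/L), mirroring how
    the label arises clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr
from scipy.stats import truncnorm

from gdmprs._rng import child_rng
from gdmprs.panel import SNPPanel, default_panel

# Diagnostic glucose cutoffs (mmol/L): fasting, 1-h and 2-h post-load.
FPG_CUTOFF = 5.5
OGTT1H_CUTOFF = 10.0
OGTT2H_CUTOFF = 8.0

#: Fixed column schema of a cohort table.
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "pbmi",
    "gravidity",
    "parity",
    "employment",
    "smoking",
    "alcohol",
    "decoration",
    "education",
    "economic",
    "physical_activity",
    "fpg",
    "ogtt_1h",
    "ogtt_2h",
    "gdm",
]


class ConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


class CalibrationError(RuntimeError):
    """Raised when intercept calibration cannot bracket the target."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distributions of the baseline covariates.

    Defaults are the control-group marginals of a Chinese antenatal cohort of
    2,258 women without GDM: age 28.99 +/- 3.54 y, pre-pregnancy BMI
    21.00 +/- 2.82 kg/m^2, and category frequencies taken from the same
    descriptive table. Continuous covariates are truncated normals; the
    truncation bounds are plausibility limits, not data-derived.
    """

    age_mean: float = 28.99
    age_sd: float = 3.54
    age_bounds: tuple[float, float] = (16.0, 50.0)
    pbmi_mean: float = 21.00
    pbmi_sd: float = 2.82
    pbmi_bounds: tuple[float, float] = (14.0, 45.0)
    # Category probabilities, control-group counts / 2258.
    gravidity_probs: tuple[float, ...] = (1402 / 2258, 477 / 2258, 379 / 2258)
    parity_probs: tuple[float, ...] = (1852 / 2258, 406 / 2258)
    employment_p: float = 1409 / 2258
    smoking_p: float = 806 / 2258
    alcohol_p: float = 66 / 2258
    decoration_p: float = 858 / 2258
    education_probs: tuple[float, ...] = (122 / 2258, 275 / 2258, 1861 / 2258)
    economic_probs: tuple[float, ...] = (
        56 / 2258,
        736 / 2258,
        1454 / 2258,
        8 / 2258,
        4 / 2258,
    )
    physical_activity_probs: tuple[float, ...] = (
        252 / 2258,
        216 / 2258,
        124 / 2258,
        62 / 2258,
        1604 / 2258,
    )


@dataclass(frozen=True)
class OgttLink:
    """Linear links from the disease linear predictor to OGTT glucose.

    ``measure = base + slope * lp + Normal(0, sd)`` (mmol/L); positive slopes
    make glucose — and hence, in threshold mode, GDM itself — increase with
    genetic and traditional risk.
    """

    fpg_base: float = 4.6
    fpg_slope: float = 0.25
    fpg_sd: float = 0.35
    ogtt_1h_base: float = 8.8
    ogtt_1h_slope: float = 1.0
    ogtt_1h_sd: float = 1.5
    ogtt_2h_base: float = 7.2
    ogtt_2h_slope: float = 0.8
    ogtt_2h_sd: float = 1.2


#: Generative log odds ratios for the multivariate disease model: per-unit
#: effects for continuous terms, indicator effects for categorical terms, and
#: a raw-score-scale effect for the PRS. Values are ln() of the odds ratios
#: from the multivariate analysis of the same cohort (PBMI 1.14/kg m^-2, age
#: 1.09/y, employment 0.75, gravidity 2 vs 1 1.43, >=3 vs 1 1.36, parity >=2
#: 0.66, PRS 19.68 per raw score unit).
DEFAULT_EFFECTS: dict[str, float] = {
    "pbmi": float(np.log(1.14)),
    "age": float(np.log(1.09)),
    "employment": float(np.log(0.75)),
    "gravidity_2": float(np.log(1.43)),
    "gravidity_ge3": float(np.log(1.36)),
    "parity_ge2": float(np.log(0.66)),
    "prs": float(np.log(19.68)),
}

#: Unadjusted quintile effects (Q2..Q5 vs Q1) for quintile outcome mode,
#: ln() of the observed quintile odds-ratio series 1.26, 1.72, 1.81, 2.01.
DEFAULT_QUINTILE_LOG_ORS: tuple[float, float, float, float] = (
    float(np.log(1.26)),
    float(np.log(1.72)),
    float(np.log(1.81)),
    float(np.log(2.01)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_subjects, seed
        Cohort size and root seed. Every stage draws from a named child
        stream of the root seed, so stages never perturb one another.
    prevalence_target
        Population GDM prevalence the intercept is calibrated to
        (default 283/2541 ~= 0.111).
    prs_mean, prs_sd
        Mean and SD of the raw score when ``prs_source="normal"``; defaults
        0.31 and 0.08 match the control-group score distribution.
    effect_spec
        Generative log-ORs by design term (see :data:`DEFAULT_EFFECTS`).
    prs_effect_mode
        ``"continuous"`` — the raw score enters the linear predictor;
        ``"quintile"`` — within-cohort score quintile indicators enter with
        ``quintile_log_ors`` and no other term contributes.
    prs_source
        ``"normal"`` draws the raw score directly; ``"genotype"`` simulates
        panel genotypes, adds imputation noise, mean-imputes missingness and
        scores them with the panel weights.
    dosage_noise_sd, missing_rate
        Imputation-noise SD (dosage units) and missing fraction applied in
        genotype mode. Defaults emulate low-pass imputation at ~0.1x depth.
    outcome_mode, ogtt_link, ogtt_shift
        See module docstring; ``ogtt_shift`` (in per-measure noise-SD units)
        moves all three glucose measures up or down and is the knob
        :func:`calibrate_ogtt_shift` solves for in threshold mode.
    copula
        Optional ``(names, correlation_matrix)`` Gaussian-copula hook that
        correlates the listed covariates; by default all covariates are
        independent (only marginals are specified by the source table).
    """

    n_subjects: int = 2541
    seed: int = 0
    prevalence_target: float = 283 / 2541
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    prs_mean: float = 0.31
    prs_sd: float = 0.08
    effect_spec: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    prs_effect_mode: str = "continuous"
    quintile_log_ors: tuple[float, ...] = DEFAULT_QUINTILE_LOG_ORS
    prs_source: str = "normal"
    panel: SNPPanel = field(default_factory=default_panel)
    dosage_noise_sd: float = 0.15
    missing_rate: float = 0.02
    outcome_mode: str = "logistic"
    ogtt_link: OgttLink = field(default_factory=OgttLink)
    ogtt_shift: float = 0.0
    copula: tuple[Sequence[str], np.ndarray] | None = None

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ConfigError("prevalence_target must lie in (0, 1)")
        if self.prs_sd <= 0:
            raise ConfigError("prs_sd must be > 0")
        if self.prs_effect_mode not in ("continuous", "quintile"):
            raise ConfigError(f"unknown prs_effect_mode {self.prs_effect_mode!r}")
        if self.prs_effect_mode == "quintile" and len(self.quintile_log_ors) != 4:
            raise ConfigError("quintile_log_ors must have 4 entries (Q2..Q5 vs Q1)")
        if self.prs_source not in ("normal", "genotype"):
            raise ConfigError(f"unknown prs_source {self.prs_source!r}")
        if self.outcome_mode not in ("logistic", "ogtt_threshold"):
            raise ConfigError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.dosage_noise_sd < 0:
            raise ConfigError("dosage_noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        spec = self.covariate_spec
        for name in (
            "gravidity_probs",
            "parity_probs",
            "education_probs",
            "economic_probs",
            "physical_activity_probs",
        ):
            p = np.asarray(getattr(spec, name), float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"category probabilities for {name.removesuffix('_probs')!r} "
                    f"must be non-negative and sum to 1 (got sum {p.sum():.12f})"
                )
        for name in ("employment_p", "smoking_p", "alcohol_p", "decoration_p"):
            p = getattr(spec, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.age_like_sd_negative():
            raise ConfigError("covariate SDs must be >= 0")

    def age_like_sd_negative(self) -> bool:
        return self.covariate_spec.age_sd < 0 or self.covariate_spec.pbmi_sd < 0


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its generative ground truth."""

    cohort: pd.DataFrame
    truth: dict
    genotypes: pd.DataFrame | None = None
    dosages: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# covariates


_CATEGORICAL_LEVELS: dict[str, list[int]] = {
    # gravidity levels 1, 2, 3 (3 encodes >=3); parity 1, 2 (2 encodes >=2)
    "gravidity": [1, 2, 3],
    "parity": [1, 2],
    "employment": [0, 1],
    "smoking": [0, 1],
    "alcohol": [0, 1],
    "decoration": [0, 1],
    "education": [0, 1, 2],
    "economic": [0, 1, 2, 3, 4],
    "physical_activity": [0, 1, 2, 3, 4],
}

#: Order in which covariates consume uniform draws (also the copula order).
_COVARIATE_ORDER = [
    "age",
    "pbmi",
    "gravidity",
    "parity",
    "employment",
    "smoking",
    "alcohol",
    "decoration",
    "education",
    "economic",
    "physical_activity",
]


def _covariate_probs(spec: CovariateSpec, name: str) -> np.ndarray:
    if name == "gravidity":
        return np.asarray(spec.gravidity_probs, float)
    if name == "parity":
        return np.asarray(spec.parity_probs, float)
    if name in ("employment", "smoking", "alcohol", "decoration"):
        p = getattr(spec, f"{name}_p")
        return np.asarray([1.0 - p, p], float)
    return np.asarray(getattr(spec, f"{name}_probs"), float)


def _uniforms(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """One uniform column per covariate, optionally copula-correlated."""
    u = pd.DataFrame(
        rng.random((n, len(_COVARIATE_ORDER))), columns=_COVARIATE_ORDER
    )
    if config.copula is not None:
        names, corr = config.copula
        names = list(names)
        unknown = set(names) - set(_COVARIATE_ORDER)
        if unknown:
            raise ConfigError(f"copula names not covariates: {sorted(unknown)}")
        corr = np.asarray(corr, float)
        if corr.shape != (len(names), len(names)):
            raise ConfigError("copula correlation matrix shape mismatch")
        chol = np.linalg.cholesky(corr)  # raises if not positive definite
        z = rng.standard_normal((n, len(names))) @ chol.T
        u[names] = ndtr(z)
    return u


def _truncnorm_from_u(
    u: np.ndarray, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    """Truncated-normal quantile transform whose *realized* mean is ``mean``.

    Truncation pulls the mean of a plain truncated normal away from its
    location parameter (about +0.05 for BMI at the default bounds), so the
    location is shifted to compensate and the configured mean is honoured.
    """
    if sd == 0.0:
        return np.full(u.shape, mean)
    lo, hi = bounds
    if not (lo < mean < hi):
        raise ConfigError(f"mean {mean} outside truncation bounds {bounds}")

    def realized_mean_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd)) - mean

    loc = brentq(realized_mean_gap, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the covariate columns of a cohort (no PRS, glucose or outcome).

    Continuous covariates are truncated normals; categorical covariates are
    multinomials with the configured probabilities. Marginals are independent
    unless a copula hook is supplied.
    """
    config.validate()
    n = config.n_subjects
    spec = config.covariate_spec
    rng = child_rng(config.seed, "covariates")
    u = _uniforms(config, n, rng)

    out = pd.DataFrame({"subject_id": [f"S{i + 1:06d}" for i in range(n)]})
    out["age"] = _truncnorm_from_u(
        u["age"].to_numpy(), spec.age_mean, spec.age_sd, spec.age_bounds
    )
    out["pbmi"] = _truncnorm_from_u(
        u["pbmi"].to_numpy(), spec.pbmi_mean, spec.pbmi_sd, spec.pbmi_bounds
    )
    for name, levels in _CATEGORICAL_LEVELS.items():
        probs = _covariate_probs(spec, name)
        if len(probs) != len(levels):
            raise ConfigError(
                f"{name}: expected {len(levels)} probabilities, got {len(probs)}"
            )
        idx = np.searchsorted(np.cumsum(probs), u[name].to_numpy(), side="right")
        idx = np.clip(idx, 0, len(levels) - 1)
        out[name] = np.asarray(levels)[idx]
    return out


# --------------------------------------------------------------------------
# genotypes and dosages


def generate_true_genotypes(
    panel: SNPPanel, n: int, seed: int
) -> pd.DataFrame:
    """Integer genotypes (effect-allele counts 0/1/2) under Hardy–Weinberg.

    Each variant is drawn independently as Binomial(2, f) with f the panel's
    effect-allele frequency.
    """
    freqs = panel.allele_freqs
    rng = child_rng(seed, "genotypes")
    geno = rng.binomial(2, freqs, size=(n, len(freqs)))
    index = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(geno, index=index, columns=panel.rsids, dtype=float)


def add_imputation_noise(
    truth: pd.DataFrame,
    noise_sd: float,
    missing_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Degrade true genotypes into imputed dosages.

    Adds Normal(0, noise_sd) to each genotype, clips to [0, 2], and sets a
    ``missing_rate`` fraction of entries missing (NaN) at random — a stand-in
    for genotype imputation from ultra-low-coverage (0.06–0.1x) sequencing.
    The input frame is not modified.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = child_rng(seed, "dosage_noise")
    values = truth.to_numpy(float)
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape), 0.0, 2.0)
    else:
        values = values.copy()
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    return pd.DataFrame(values, index=truth.index, columns=truth.columns)


# --------------------------------------------------------------------------
# linear predictor and intercept calibration


def _term_values(cohort: pd.DataFrame, prs: np.ndarray | None, term: str) -> np.ndarray:
    if term == "prs":
        if prs is None:
            raise ValueError("effect_spec references 'prs' but no scores were given")
        return np.asarray(prs, float)
    if term == "gravidity_2":
        return (cohort["gravidity"].to_numpy() == 2).astype(float)
    if term == "gravidity_ge3":
        return (cohort["gravidity"].to_numpy() == 3).astype(float)
    if term == "parity_ge2":
        return (cohort["parity"].to_numpy() == 2).astype(float)
    if term in cohort.columns:
        return cohort[term].to_numpy(float)
    raise ConfigError(f"unknown effect term {term!r}")


def _quintile_eta(prs: np.ndarray, quintile_log_ors: Sequence[float]) -> np.ndarray:
    from gdmprs.prs import assign_quintiles  # local import to avoid a cycle

    q = assign_quintiles(pd.DataFrame({"raw_score": prs}))["quintile"].to_numpy()
    betas = np.concatenate([[0.0], np.asarray(quintile_log_ors, float)])
    return betas[q - 1]


def linear_predictor(
    cohort: pd.DataFrame, prs: np.ndarray | None, config: GeneratorConfig
) -> np.ndarray:
    """Intercept-free linear predictor eta = sum beta_j x_j for a cohort."""
    if config.prs_effect_mode == "quintile":
        if prs is None:
            raise ValueError("quintile mode needs scores")
        return _quintile_eta(np.asarray(prs, float), config.quintile_log_ors)
    eta = np.zeros(len(cohort))
    for term, beta in config.effect_spec.items():
        eta += beta * _term_values(cohort, prs, term)
    return eta


def _draw_prs(config: GeneratorConfig, n: int, seed: int) -> np.ndarray:
    """Raw scores for n subjects, by direct Normal draw or via genotypes."""
    if config.prs_source == "normal":
        rng = child_rng(seed, "prs")
        return rng.normal(config.prs_mean, config.prs_sd, n)
    from gdmprs.prs import compute_prs
    from gdmprs.qc import impute_missing_dosages

    truth = generate_true_genotypes(config.panel, n, seed)
    dosages = add_imputation_noise(
        truth, config.dosage_noise_sd, config.missing_rate, seed
    )
    return compute_prs(impute_missing_dosages(dosages), config.panel)[
        "raw_score"
    ].to_numpy()


def calibrate_intercept(
    config: GeneratorConfig,
    pool_size: int = 200_000,
    bracket: tuple[float, float] = (-40.0, 10.0),
) -> float:
    """Root-find the logistic intercept hitting ``prevalence_target``.

    A Monte-Carlo pool of covariates and scores is drawn from dedicated
    calibration streams (so calibration never consumes cohort randomness) and
    the intercept solves mean(expit(b0 + eta)) = target over the pool.
    """
    config.validate()
    if pool_size < 100_000:
        raise ValueError("calibration pool must hold at least 1e5 subjects")
    pool_cfg = replace(config, n_subjects=pool_size, seed=config.seed)
    rng = child_rng(config.seed, "calibrate.covariates")
    u = _uniforms(pool_cfg, pool_size, rng)
    spec = config.covariate_spec
    pool = pd.DataFrame(
        {
            "age": _truncnorm_from_u(
                u["age"].to_numpy(), spec.age_mean, spec.age_sd, spec.age_bounds
            ),
            "pbmi": _truncnorm_from_u(
                u["pbmi"].to_numpy(), spec.pbmi_mean, spec.pbmi_sd, spec.pbmi_bounds
            ),
        }
    )
    for name, levels in _CATEGORICAL_LEVELS.items():
        probs = _covariate_probs(spec, name)
        idx = np.searchsorted(np.cumsum(probs), u[name].to_numpy(), side="right")
        pool[name] = np.asarray(levels)[np.clip(idx, 0, len(levels) - 1)]
    prs_rng = child_rng(config.seed, "calibrate.prs")
    if config.prs_source == "normal":
        prs = prs_rng.normal(config.prs_mean, config.prs_sd, pool_size)
    else:
        freqs = config.panel.allele_freqs
        geno = prs_rng.binomial(2, freqs, size=(pool_size, len(freqs))).astype(float)
        if config.dosage_noise_sd > 0:
            geno = np.clip(
                geno + prs_rng.normal(0.0, config.dosage_noise_sd, geno.shape), 0, 2
            )
        prs = geno @ config.panel.weights
    eta = linear_predictor(pool, prs, config)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - config.prevalence_target

    lo, hi = bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"intercept bracket {bracket} does not contain the target prevalence"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def calibrate_ogtt_shift(
    config: GeneratorConfig, pool_size: int = 200_000
) -> float:
    """Common glucose shift (noise-SD units) hitting the target prevalence
    in ``ogtt_threshold`` mode.

    The shift delta moves every measure by ``delta * sd_measure`` before
    thresholding; it is solved on a Monte-Carlo pool by bisection.
    """
    config.validate()
    pool_cfg = replace(
        config, n_subjects=pool_size, outcome_mode="ogtt_threshold", ogtt_shift=0.0
    )
    pool = generate_covariates(replace(pool_cfg, seed=config.seed + 1))
    prs = _draw_prs(pool_cfg, pool_size, config.seed + 1)
    eta = linear_predictor(pool, prs, config)
    link = config.ogtt_link
    rng = child_rng(config.seed, "calibrate.ogtt")
    noise = rng.standard_normal((pool_size, 3))
    base = np.array([link.fpg_base, link.ogtt_1h_base, link.ogtt_2h_base])
    slope = np.array([link.fpg_slope, link.ogtt_1h_slope, link.ogtt_2h_slope])
    sd = np.array([link.fpg_sd, link.ogtt_1h_sd, link.ogtt_2h_sd])
    cut = np.array([FPG_CUTOFF, OGTT1H_CUTOFF, OGTT2H_CUTOFF])
    glucose0 = base + slope * eta[:, None] + sd * noise

    def gap(delta: float) -> float:
        g = glucose0 + delta * sd
        return float(np.mean((g >= cut).any(axis=1))) - config.prevalence_target

    lo, hi = -20.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError("glucose shift bracket does not contain the target")
    return float(brentq(gap, lo, hi, xtol=1e-8))


# --------------------------------------------------------------------------
# outcome


def generate_outcome(
    cohort: pd.DataFrame,
    prs: np.ndarray | pd.DataFrame | None,
    config: GeneratorConfig,
    intercept: float | None = None,
) -> pd.DataFrame:
    """Fill GDM labels and OGTT glucose for a covariate table.

    In logistic mode the calibrated ``intercept`` is required (calibrate with
    :func:`calibrate_intercept`); glucose is a positive linear function of the
    full linear predictor plus noise, so corr(PRS, glucose) > 0 whenever the
    link slopes are positive. In threshold mode GDM is defined by the
    diagnostic cutoffs applied to the generated glucose.
    """
    config.validate()
    if isinstance(prs, pd.DataFrame):
        prs = prs["raw_score"].to_numpy()
    prs = None if prs is None else np.asarray(prs, float)
    eta = linear_predictor(cohort, prs, config)
    out = cohort.copy()
    if prs is not None:
        out["prs"] = prs
    link = config.ogtt_link
    rng = child_rng(config.seed, "outcome")
    ogtt_rng = child_rng(config.seed, "ogtt")
    noise = ogtt_rng.standard_normal((len(cohort), 3))
    base = np.array([link.fpg_base, link.ogtt_1h_base, link.ogtt_2h_base])
    slope = np.array([link.fpg_slope, link.ogtt_1h_slope, link.ogtt_2h_slope])
    sd = np.array([link.fpg_sd, link.ogtt_1h_sd, link.ogtt_2h_sd])

    if config.outcome_mode == "logistic":
        if intercept is None:
            raise RuntimeError(
                "logistic outcome mode needs a calibrated intercept; "
                "call calibrate_intercept(config) first"
            )
        lp = intercept + eta
        out["gdm"] = (rng.random(len(cohort)) < expit(lp)).astype(int)
        glucose = base + slope * lp[:, None] + sd * (noise + config.ogtt_shift)
    else:
        glucose = base + slope * eta[:, None] + sd * (noise + config.ogtt_shift)
        cut = np.array([FPG_CUTOFF, OGTT1H_CUTOFF, OGTT2H_CUTOFF])
        out["gdm"] = (glucose >= cut).any(axis=1).astype(int)
    glucose = np.maximum(glucose, 0.1)  # glucose must stay positive
    out["fpg"], out["ogtt_1h"], out["ogtt_2h"] = glucose.T
    return out


def generate_cohort(
    config: GeneratorConfig,
    intercept: float | None = None,
    keep_genotypes: bool = False,
) -> SyntheticCohort:
    """Generate a complete cohort: covariates, PRS, glucose and GDM labels.

    Passing a pre-computed ``intercept`` skips re-calibration (useful when
    generating many replicate cohorts under one configuration).
    """
    config.validate()
    cohort = generate_covariates(config)
    genotypes = dosages = None
    if config.prs_source == "genotype":
        genotypes = generate_true_genotypes(config.panel, config.n_subjects, config.seed)
        dosages = add_imputation_noise(
            genotypes, config.dosage_noise_sd, config.missing_rate, config.seed
        )
        from gdmprs.prs import compute_prs
        from gdmprs.qc import impute_missing_dosages

        prs = compute_prs(impute_missing_dosages(dosages), config.panel)[
            "raw_score"
        ].to_numpy()
    else:
        prs = _draw_prs(config, config.n_subjects, config.seed)
    if config.outcome_mode == "logistic" and intercept is None:
        intercept = calibrate_intercept(config)
    cohort = generate_outcome(cohort, prs, config, intercept=intercept)
    truth = {
        "intercept": intercept,
        "effect_spec": dict(config.effect_spec),
        "prs_effect_mode": config.prs_effect_mode,
        "quintile_log_ors": list(config.quintile_log_ors),
        "prevalence_target": config.prevalence_target,
        "prs_mean": config.prs_mean,
        "prs_sd": config.prs_sd,
        "outcome_mode": config.outcome_mode,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
    }
    if keep_genotypes:
        return SyntheticCohort(cohort, truth, genotypes=genotypes, dosages=dosages)
    return SyntheticCohort(cohort, truth)


def closed_form_intercept(prevalence: float) -> float:
    """logit(prevalence): the exact intercept when every effect is zero."""
    return float(logit(prevalence))
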