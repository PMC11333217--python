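"""End-to-end orchestration: simulate (or load) -> QC -> PRS -> models -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gdmprs import __version__, io
from gdmprs.association import (
    TRADITIONAL_TERMS,
    build_design,
    fit_logistic,
    prs_glucose_correlation,
    quintile_association,
    univariate_screen,
)
from gdmprs.compare import cv_undersample_evaluate, roc_auc
from gdmprs.panel import SNPPanel, default_panel
from gdmprs.prs import score_panel
from gdmprs.qc import impute_missing_dosages, read_dosages, sample_qc, variant_qc
from gdmprs.simulate import GeneratorConfig, generate_cohort

log = logging.getLogger("gdmprs")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either real-data paths (``genotypes_path`` + ``cohort_path``) or the
    generator block is used; with no paths a synthetic cohort is generated.
    """

    out_dir: str = "gdmprs_out"
    seed: int = 0
    panel_path: str | None = None
    genotypes_path: str | None = None
    cohort_path: str | None = None
    sample_qc_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    missing_max: float = 0.1
    model_terms: list[str] = field(default_factory=lambda: list(TRADITIONAL_TERMS))
    prs_scale: str = "raw"
    nri_variant: str = "continuous"
    nri_thresholds: list[float] | None = None
    cv_folds: int = 5
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", {})
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_json_dict(self) -> dict:
        def conv(x):
            if is_dataclass(x) and not isinstance(x, type):
                try:
                    return {k: conv(v) for k, v in asdict(x).items()}
                except TypeError:
                    return str(x)
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            if isinstance(x, tuple):
                return [conv(v) for v in x]
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            return x

        d = {k: conv(v) for k, v in self.__dict__.items()}
        # the generator's panel is summarized by its table
        d["generator"]["panel"] = self.generator.panel.table.to_dict(orient="records")
        return d


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis configuration (output location excluded)."""
    d = config.to_json_dict()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def summarize_table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table by GDM status: mean +/- SD or n (%), with p-values."""
    y = cohort["gdm"].to_numpy(int)
    two_class = len(np.unique(y)) == 2
    screen = (
        univariate_screen(cohort).set_index("variable") if two_class else None
    )
    groups = {"non_gdm": cohort[y == 0], "gdm": cohort[y == 1]}
    rows = []

    def pval(name: str) -> float:
        if screen is not None and name in screen.index:
            return float(screen.loc[name, "p"])
        return float("nan")

    for name in ("pbmi", "age"):
        row = {"variable": name, "level": ""}
        for g, frame in groups.items():
            row[g] = (
                f"{frame[name].mean():.2f}±{frame[name].std(ddof=1):.2f}"
                if len(frame)
                else "NA"
            )
        row["p"] = pval(name)
        rows.append(row)
    categoricals = {
        "gravidity": [1, 2, 3],
        "parity": [1, 2],
        "decoration": [0, 1],
        "smoking": [0, 1],
        "physical_activity": [0, 1, 2, 3, 4],
        "alcohol": [0, 1],
        "employment": [0, 1],
        "education": [0, 1, 2],
        "economic": [0, 1, 2, 3, 4],
    }
    for name, levels in categoricals.items():
        for i, level in enumerate(levels):
            row = {"variable": name, "level": str(level)}
            for g, frame in groups.items():
                n = int((frame[name] == level).sum())
                pct = 100.0 * n / len(frame) if len(frame) else 0.0
                row[g] = f"{n} ({pct:.1f}%)"
            row["p"] = pval(name) if i == 0 else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a manifest dict (also written to ``manifest.json``) with stage
    counts, the config hash and library versions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "gdmprs": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    panel = (
        SNPPanel.from_tsv(config.panel_path) if config.panel_path else default_panel()
    )
    if config.panel_path is None and config.genotypes_path is not None:
        raise FileNotFoundError("a panel file is required to score real genotypes")

    # --- stage: data (simulate or load) ------------------------------------
    if config.cohort_path is None:
        gen = config.generator
        if gen.seed != config.seed:
            from dataclasses import replace

            gen = replace(gen, seed=config.seed)
        sim = generate_cohort(gen, keep_genotypes=True)
        cohort = sim.cohort
        io.write_cohort(cohort, out / "cohort.tsv")
        io.write_json(sim.truth, out / "truth.json")
        if sim.dosages is not None:
            io.write_vcf(sim.dosages, gen.panel, out / "genotypes.vcf")
            dosages = sim.dosages
            panel = gen.panel
        else:
            dosages = None
        log.info("simulated cohort: n=%d, cases=%d", len(cohort), cohort["gdm"].sum())
    else:
        cohort = io.read_cohort(config.cohort_path)
        dosages = None
        if config.genotypes_path is not None:
            result = read_dosages(config.genotypes_path, panel)
            if result.absent:
                log.warning("panel SNPs absent from genotypes: %s", result.absent)
            dosages = result.dosages
    manifest["stages"]["data"] = {"n_subjects": int(len(cohort))}

    # --- stage: QC ---------------------------------------------------------
    if config.sample_qc_path is not None and dosages is not None:
        records = pd.read_csv(config.sample_qc_path, sep="\t")
        kept, sample_report = sample_qc(records)
        dosages = dosages.loc[dosages.index.intersection(kept)]
        io.write_qc_report(sample_report, out / "sample_qc")
        manifest["stages"]["sample_qc"] = {
            "n_in": sample_report.n_samples_in,
            "n_pass": sample_report.n_samples_pass,
        }
    if dosages is not None:
        filtered, report = variant_qc(
            dosages, config.maf_min, config.hwe_p_min, config.missing_max
        )
        io.write_qc_report(report, out / "variant_qc")
        manifest["stages"]["variant_qc"] = {
            "n_in": report.n_variants_in,
            "n_pass": report.n_variants_pass,
        }
        if report.n_variants_pass < len(panel):
            log.warning(
                "%d panel SNPs failed QC", len(panel) - report.n_variants_pass
            )

    # --- stage: PRS --------------------------------------------------------
    if dosages is not None and not dosages.empty:
        scores = score_panel(impute_missing_dosages(dosages), panel)
        scores = scores.iloc[: len(cohort)]
    elif "prs" in cohort.columns:
        from gdmprs.prs import assign_quintiles, standardize

        scores = assign_quintiles(
            standardize(pd.DataFrame({"raw_score": cohort["prs"].to_numpy()}))
        )
    else:
        raise ValueError("no genotypes and no PRS column: cannot score subjects")
    io.write_scores(scores, out / "scores.tsv")

    # --- stage: screening & descriptives -----------------------------------
    screen = univariate_screen(cohort)
    screen.to_csv(out / "screening.tsv", sep="\t", index=False)
    summarize_table1(cohort).to_csv(out / "table1.tsv", sep="\t", index=False)
    manifest["stages"]["screening"] = {
        "n_selected": int(screen["selected"].sum())
    }

    # --- stage: models -----------------------------------------------------
    X = build_design(cohort, config.model_terms + ["prs"], prs=scores, prs_scale=config.prs_scale)
    fit = fit_logistic(X, cohort["gdm"].to_numpy())
    fit.summary().to_csv(out / "multivariate_fit.tsv", sep="\t")
    manifest["stages"]["multivariate"] = {
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }
    quintiles = quintile_association(cohort, scores)
    quintiles.to_csv(out / "quintile_association.tsv", sep="\t", index=False)
    corr = prs_glucose_correlation(scores, cohort)
    corr.to_csv(out / "prs_glucose_correlation.tsv", sep="\t", index=False)

    # --- stage: comparison -------------------------------------------------
    report = cv_undersample_evaluate(
        cohort,
        scores,
        k=config.cv_folds,
        seed=config.seed,
        n_boot=config.n_boot,
        nri_variant=config.nri_variant,
        nri_thresholds=config.nri_thresholds,
    )
    io.write_json(report.to_json_dict(), out / "comparison.json")
    report.cv_folds.to_csv(out / "comparison_cv_folds.tsv", sep="\t", index=False)
    for name in report.model_specs:
        terms = report.model_specs[name]
        Xm = build_design(cohort, terms, prs=scores, prs_scale=config.prs_scale)
        fm = fit_logistic(Xm, cohort["gdm"].to_numpy())
        from gdmprs.association import predict_proba

        io.write_roc_curve(
            roc_auc(predict_proba(fm, Xm), cohort["gdm"].to_numpy()),
            out / f"roc_{name}.tsv",
        )
    manifest["stages"]["comparison"] = {
        "cv_folds": config.cv_folds,
        "n_boot": config.n_boot,
    }

    io.write_json(manifest, out / "manifest.json")
    return manifest
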