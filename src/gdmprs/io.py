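"""Readers and writers for the package's on-disk formats.

Cohorts are tab-separated tables with a fixed header schema; genotype dosages
are written as minimal VCF 4.2 with a ``DS`` FORMAT field; panels, scores and
QC reports are TSV; generative ground truth travels as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gdmprs.panel import SNPPanel
from gdmprs.qc import QCReport
from gdmprs.simulate import COHORT_COLUMNS

_COHORT_ORDER = COHORT_COLUMNS + ["prs"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _COHORT_ORDER if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", "gdm") if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if cohort["gdm"].isna().any():
        raise ValueError("cohort table has missing GDM labels")
    return cohort


def write_vcf(dosages: pd.DataFrame, panel: SNPPanel, path: str | Path) -> None:
    """Write effect-allele dosages as VCF 4.2 (ALT = effect allele, FORMAT DS)."""
    table = panel.table.set_index("rsid")
    samples = list(dosages.index)
    chroms = sorted({str(table.loc[r, "chrom"]) for r in dosages.columns})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gdmprs\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Imputed dosage of the ALT allele (0..2)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = sorted(
            dosages.columns, key=lambda r: (str(table.loc[r, "chrom"]), int(table.loc[r, "pos"]))
        )
        for rsid in order:
            row = table.loc[rsid]
            ds = dosages[rsid].to_numpy(float)
            entries = [("." if np.isnan(d) else f"{d:.4f}") for d in ds]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\tPASS\t.\tDS\t" + "\t".join(entries) + "\n"
            )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.reset_index()
    out = out.rename(columns={out.columns[0]: "subject_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_qc_report(report: QCReport, stem: str | Path) -> None:
    stem = Path(stem)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=float)
    if report.variants is not None:
        report.variants.to_csv(stem.with_suffix(".variants.tsv"), sep="\t", index=False)
    if report.samples is not None:
        report.samples.to_csv(stem.with_suffix(".samples.tsv"), sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    def default(x):
        if isinstance(x, (np.floating, np.integer)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, sort_keys=True)


def write_roc_curve(curve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "one_minus_specificity": curve.one_minus_specificity,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
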