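"""Genotype quality control on imputed allele dosages.

Sample level: exclude samples with sequencing depth < 0.05x or mapping rate
< 90% (strict exclusion — boundary values are kept). Variant level: keep a
variant iff MAF > 0.05, exact Hardy–Weinberg p > 1e-6 and missing rate < 0.1
(all strict retention). MAF is computed from mean dosage (using the full
information in imputed dosages); the HWE exact test runs on hard calls
(dosages rounded to the nearest integer, .5 rounding up) because the exact
test is defined on genotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from gdmprs.panel import SNPPanel

# Default thresholds.
DEPTH_MIN = 0.05
MAPRATE_MIN = 0.90
MAF_MIN = 0.05
HWE_P_MIN = 1e-6
MISSING_MAX = 0.1


class DosageReadError(ValueError):
    """Raised for unparseable dosage files or allele mismatches."""


class ReadResult(NamedTuple):
    """Effect-allele-oriented dosages plus panel SNPs absent from the file."""

    dosages: pd.DataFrame
    absent: list[str]


@dataclass
class QCReport:
    """Per-sample and/or per-variant QC metrics with pass flags."""

    samples: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None

    @property
    def n_samples_in(self) -> int:
        return 0 if self.samples is None else len(self.samples)

    @property
    def n_samples_pass(self) -> int:
        return 0 if self.samples is None else int(self.samples["pass"].sum())

    @property
    def n_variants_in(self) -> int:
        return 0 if self.variants is None else len(self.variants)

    @property
    def n_variants_pass(self) -> int:
        return 0 if self.variants is None else int(self.variants["pass"].sum())

    def to_json_dict(self) -> dict:
        out: dict = {
            "n_samples_in": self.n_samples_in,
            "n_samples_pass": self.n_samples_pass,
            "n_variants_in": self.n_variants_in,
            "n_variants_pass": self.n_variants_pass,
        }
        if self.variants is not None:
            out["variants"] = self.variants.to_dict(orient="records")
        if self.samples is not None:
            out["samples"] = self.samples.to_dict(orient="records")
        return out


# --------------------------------------------------------------------------
# readers


def _read_dosages_vcf(path: str | Path, panel: SNPPanel) -> ReadResult:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_rsid = panel.table.set_index("rsid")
    by_pos = {
        (str(r.chrom), int(r.pos)): rsid for rsid, r in by_rsid.iterrows()
    }
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID if variant.ID in by_rsid.index else by_pos.get(
            (str(variant.CHROM), int(variant.POS))
        )
        if rsid is None:
            continue
        row = by_rsid.loc[rsid]
        if len(variant.ALT) != 1:
            raise DosageReadError(f"{rsid}: panel variants must be biallelic")
        ref, alt = variant.REF, variant.ALT[0]
        if (ref, alt) == (row["other_allele"], row["effect_allele"]):
            flip = False
        elif (ref, alt) == (row["effect_allele"], row["other_allele"]):
            flip = True
        else:
            raise DosageReadError(
                f"{rsid}: file alleles {ref}/{alt} match neither orientation of "
                f"panel alleles {row['effect_allele']}/{row['other_allele']}"
            )
        ds = variant.format("DS")
        if ds is None:
            raise DosageReadError(f"{rsid}: no DS (dosage) FORMAT field")
        ds = np.asarray(ds, float).reshape(len(samples))
        ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, ds)  # cyvcf2 missing sentinel
        columns[rsid] = 2.0 - ds if flip else ds
    absent = [r for r in panel.rsids if r not in columns]
    frame = pd.DataFrame(
        {r: columns[r] for r in panel.rsids if r in columns},
        index=pd.Index(samples, name="sample_id"),
    )
    return ReadResult(frame, absent)


def _read_dosages_table(path: str | Path, panel: SNPPanel) -> ReadResult:
    try:
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise DosageReadError(f"cannot parse dosage table {path}: {exc}") from exc
    frame.index.name = "sample_id"
    absent = [r for r in panel.rsids if r not in frame.columns]
    present = [r for r in panel.rsids if r in frame.columns]
    frame = frame[present].astype(float)
    bad = (frame < 0) | (frame > 2)
    if bad.any().any():
        raise DosageReadError("dosage table holds values outside [0, 2]")
    return ReadResult(frame, absent)


def read_dosages(path: str | Path, panel: SNPPanel) -> ReadResult:
    """Read panel dosages from a VCF (FORMAT ``DS``) or a delimited table.

    VCF dosages are re-oriented to count the panel's effect allele: when the
    file's ALT allele is the panel's *other* allele the stored dosage becomes
    ``2 - DS``. A site whose REF/ALT pair matches neither orientation raises
    :class:`DosageReadError`. Delimited tables (samples x rsids, first column
    sample ids) are assumed already effect-allele oriented. Panel SNPs absent
    from the file are returned in ``absent``, never silently dropped.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_dosages_vcf(path, panel)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_dosages_vcf(path, panel)
    return _read_dosages_table(path, panel)


# --------------------------------------------------------------------------
# sample QC


def sample_qc(
    records: pd.DataFrame | Sequence[tuple],
    depth_min: float = DEPTH_MIN,
    maprate_min: float = MAPRATE_MIN,
) -> tuple[list[str], QCReport]:
    """Keep samples with depth >= depth_min and mapping rate >= maprate_min.

    ``records`` is a frame (or sequence of tuples) with columns
    ``sample_id``, ``mean_depth``, ``mapping_rate``. Exclusion is strict
    (a sample exactly at a threshold is kept).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            records, columns=["sample_id", "mean_depth", "mapping_rate"]
        )
    if records["sample_id"].duplicated().any():
        dups = records.loc[records["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if (records["mean_depth"] < 0).any():
        raise ValueError("mean_depth must be >= 0")
    if ((records["mapping_rate"] < 0) | (records["mapping_rate"] > 1)).any():
        raise ValueError("mapping_rate must lie in [0, 1]")
    table = records.copy()
    table["pass_depth"] = table["mean_depth"] >= depth_min
    table["pass_maprate"] = table["mapping_rate"] >= maprate_min
    table["pass"] = table["pass_depth"] & table["pass_maprate"]
    kept = table.loc[table["pass"], "sample_id"].tolist()
    return kept, QCReport(samples=table)


# --------------------------------------------------------------------------
# exact Hardy–Weinberg test


def _hwe_het_log_pmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of the heterozygote count conditional on allele counts.

    Given n diploid genotypes carrying ``n_minor`` copies of the minor allele,
    the attainable heterozygote counts share the parity of ``n_minor`` and the
    probability of k heterozygotes is

        P(k) = 2^k * n! / (n_hom_min! k! n_hom_maj!) * n_minor! n_major! / (2n)!

    with n_hom_min = (n_minor - k)/2 homozygous-minor genotypes.
    """
    n_major = 2 * n - n_minor
    k_max = min(n_minor, n_major)
    ks = np.arange(n_minor % 2, k_max + 1, 2)
    hom_min = (n_minor - ks) // 2
    hom_maj = (n_major - ks) // 2
    logp = (
        ks * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_min + 1)
        - gammaln(ks + 1)
        - gammaln(hom_maj + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    logp -= np.log(np.exp(logp - logp.max()).sum()) + logp.max()  # normalize
    return ks, logp


def hwe_exact_pvalues(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE p-value for every attainable heterozygote count.

    Returns ``(het_counts, p_values)``; the p-value at k sums the
    probabilities of all heterozygote counts no more likely than k.
    """
    ks, logp = _hwe_het_log_pmf(n, n_minor)
    p = np.exp(logp)
    # Sum over counts with probability <= P(obs), with a relative tolerance
    # so exact float ties are included on both sides.
    pvals = np.array([p[p <= pk * (1.0 + 1e-12)].sum() for pk in p])
    return ks, np.minimum(pvals, 1.0)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy–Weinberg equilibrium on genotype counts.

    The p-value is the total probability, conditional on the allele counts,
    of heterozygote counts no more likely than the observed one. Monomorphic
    input has a single attainable configuration and returns 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts)
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    ks, pvals = hwe_exact_pvalues(n, n_minor)
    return float(pvals[np.searchsorted(ks, n_het)])


# --------------------------------------------------------------------------
# variant QC and imputation


def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to genotype calls 0/1/2; ties at .5 round half up."""
    return np.clip(np.floor(dosages + 0.5), 0, 2)


def variant_qc(
    matrix: pd.DataFrame,
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
    missing_max: float = MISSING_MAX,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter variants on MAF, exact HWE and missingness (all strict).

    MAF is min(m, 1-m) with m = mean(non-missing dosage)/2; the HWE test uses
    hard calls from the non-missing dosages. A variant with every entry
    missing fails the missingness filter (its MAF/HWE are reported as NaN).
    """
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ValueError("dosage matrix must be non-empty")
    rows = []
    for rsid in matrix.columns:
        d = matrix[rsid].to_numpy(float)
        miss = float(np.isnan(d).mean())
        obs = d[~np.isnan(d)]
        if obs.size == 0:
            maf = hwe_p = float("nan")
        else:
            m = float(obs.mean()) / 2.0
            maf = min(m, 1.0 - m)
            calls = hard_calls(obs)
            hwe_p = hwe_exact_test(
                int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())
            )
        ok = (
            obs.size > 0
            and maf > maf_min
            and hwe_p > hwe_p_min
            and miss < missing_max
        )
        rows.append(
            {
                "rsid": rsid,
                "maf": maf,
                "hwe_p": hwe_p,
                "missing_rate": miss,
                "pass_maf": obs.size > 0 and maf > maf_min,
                "pass_hwe": obs.size > 0 and hwe_p > hwe_p_min,
                "pass_missing": miss < missing_max,
                "pass": bool(ok),
            }
        )
    report = pd.DataFrame(rows)
    kept = report.loc[report["pass"], "rsid"].tolist()
    return matrix[kept], QCReport(variants=report)


def impute_missing_dosages(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosages by the variant's mean observed dosage."""
    return matrix.fillna(matrix.mean(axis=0))
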