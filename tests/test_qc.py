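"""Genotype QC: readers, sample/variant filters, exact Hardy–Weinberg test."""

import math

import numpy as np
import pandas as pd
import pytest

from gdmprs.panel import SNPPanel, default_panel
from gdmprs.qc import (
    DosageReadError,
    hard_calls,
    hwe_exact_pvalues,
    hwe_exact_test,
    impute_missing_dosages,
    read_dosages,
    sample_qc,
    variant_qc,
)

# --------------------------------------------------------------------------
# independent HWE oracle: direct enumeration with lgamma arithmetic


def hwe_pmf_oracle(n: int, n_minor: int) -> dict[int, float]:
    """P(k heterozygotes | n genotypes, n_minor minor alleles), enumerated."""
    n_major = 2 * n - n_minor
    pmf = {}
    for k in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        hom_min = (n_minor - k) // 2
        hom_maj = (n_major - k) // 2
        logp = (
            k * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(hom_min + 1)
            - math.lgamma(k + 1)
            - math.lgamma(hom_maj + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(n_major + 1)
            - math.lgamma(2 * n + 1)
        )
        pmf[k] = math.exp(logp)
    total = sum(pmf.values())
    return {k: p / total for k, p in pmf.items()}


def hwe_p_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * n_bb
    n_minor = min(nb, 2 * n - nb)
    if n_minor == 0:
        return 1.0
    pmf = hwe_pmf_oracle(n, n_minor)
    p_obs = pmf[n_ab]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12)))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(40, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 17) == 1.0

    def test_balanced_matches_enumeration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_p_oracle(25, 50, 25), rel=1e-10
        )

    def test_extreme_het_deficit_fails_filter(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_symmetry_in_homozygote_labels(self):
        assert hwe_exact_test(30, 20, 10) == pytest.approx(
            hwe_exact_test(10, 20, 30), rel=1e-12
        )

    def test_exhaustive_small_grid(self):
        """Every genotype configuration with total <= 25 matches enumeration."""
        for n in range(1, 26):
            for n_bb in range(n + 1):
                for n_ab in range(n - n_bb + 1):
                    n_aa = n - n_bb - n_ab
                    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_p_oracle(n_aa, n_ab, n_bb), rel=1e-9
                    ), (n_aa, n_ab, n_bb)

    def test_all_allele_counts_up_to_200(self):
        """p-values for every attainable het count agree with enumeration for
        all totals up to 200 (covering every genotype triple exhaustively)."""
        for n in range(1, 201, 1):
            for n_minor in range(1, n + 1, max(1, n // 13)):
                ks, pvals = hwe_exact_pvalues(n, n_minor)
                pmf = hwe_pmf_oracle(n, n_minor)
                assert list(ks) == sorted(pmf)
                p_sorted = np.array([pmf[k] for k in ks])
                expect = np.array(
                    [p_sorted[p_sorted <= pk * (1 + 1e-12)].sum() for pk in p_sorted]
                )
                np.testing.assert_allclose(pvals, np.minimum(expect, 1.0), rtol=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestSampleQC:
    @pytest.mark.parametrize(
        "depth,rate,kept",
        [
            (0.06, 0.95, True),   # inside the retained depth range
            (0.05, 0.90, True),   # boundary values kept: exclusion is strict <
            (0.04, 0.99, False),  # fails depth
            (0.10, 0.89, False),  # fails mapping rate
        ],
    )
    def test_thresholds(self, depth, rate, kept):
        ids, report = sample_qc([("s1", depth, rate)])
        assert (ids == ["s1"]) is kept
        assert report.n_samples_in == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sample_qc([("s1", 0.1, 0.95), ("s1", 0.2, 0.99)])

    def test_counts_reconcile(self, rng):
        records = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(100)],
                "mean_depth": rng.uniform(0.02, 0.12, 100),
                "mapping_rate": rng.uniform(0.85, 1.0, 100),
            }
        )
        kept, report = sample_qc(records)
        assert len(kept) == report.n_samples_pass
        assert report.n_samples_in == 100
        assert report.n_samples_in - report.n_samples_pass == (
            (~report.samples["pass"]).sum()
        )


def _hwe_column(rng, n, f):
    g = rng.binomial(2, f, n).astype(float)
    return g


class TestVariantQC:
    def test_maximal_maf_kept(self, rng):
        col = _hwe_column(rng, 1000, 0.5)
        m = pd.DataFrame({"snp": col})
        kept, report = variant_qc(m)
        assert list(kept.columns) == ["snp"]
        assert report.variants.loc[0, "maf"] == pytest.approx(0.5, abs=0.05)

    def test_low_maf_removed(self):
        m = pd.DataFrame({"snp": np.array([0.08] * 100)})  # mean dosage 0.08
        kept, report = variant_qc(m)
        assert kept.shape[1] == 0
        assert not report.variants.loc[0, "pass_maf"]

    def test_planted_violations(self, rng):
        """20 variants, 6 planted to break exactly one filter each: 14 pass."""
        n = 600
        cols = {}
        for i in range(14):
            cols[f"ok{i}"] = _hwe_column(rng, n, 0.4)
        for i in range(2):  # low MAF
            cols[f"maf{i}"] = rng.binomial(2, 0.01, n).astype(float)
        for i in range(2):  # HWE: all heterozygotes
            cols[f"hwe{i}"] = np.ones(n)
        for i in range(2):  # missingness 20%
            col = _hwe_column(rng, n, 0.4)
            col[: n // 5] = np.nan
            cols[f"miss{i}"] = col
        kept, report = variant_qc(pd.DataFrame(cols))
        assert kept.shape[1] == 14
        assert set(kept.columns) == {f"ok{i}" for i in range(14)}
        assert report.n_variants_in - report.n_variants_pass == 6

    def test_all_missing_fails_missingness(self):
        m = pd.DataFrame({"good": np.ones(50) * 0.9, "bad": np.full(50, np.nan)})
        m["good"] = _hwe_column(np.random.default_rng(0), 50, 0.5)
        kept, report = variant_qc(m)
        row = report.variants.set_index("rsid").loc["bad"]
        assert not row["pass_missing"]
        assert "bad" not in kept.columns

    def test_idempotent(self, rng):
        m = pd.DataFrame({f"s{i}": _hwe_column(rng, 400, 0.3) for i in range(8)})
        m.iloc[:30, 2] = np.nan
        once, r1 = variant_qc(m)
        twice, r2 = variant_qc(once)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.n_variants_in == r2.n_variants_pass

    def test_counts_reconcile(self, rng):
        m = pd.DataFrame({f"s{i}": _hwe_column(rng, 200, 0.2) for i in range(10)})
        kept, report = variant_qc(m)
        assert kept.shape[1] == report.n_variants_pass
        assert report.n_variants_in == 10

    def test_hard_calls_round_half_up(self):
        np.testing.assert_array_equal(
            hard_calls(np.array([0.49, 0.5, 1.49, 1.5, 2.0])),
            np.array([0.0, 1.0, 1.0, 2.0, 2.0]),
        )


class TestImputeMissing:
    def test_identity_without_missing(self, rng):
        m = pd.DataFrame({"a": rng.uniform(0, 2, 20)})
        pd.testing.assert_frame_equal(impute_missing_dosages(m), m)

    def test_simple_mean(self):
        m = pd.DataFrame({"a": [0.0, 2.0, np.nan]})
        assert impute_missing_dosages(m).loc[2, "a"] == 1.0

    def test_column_means_preserved(self, rng):
        m = pd.DataFrame({f"s{i}": rng.uniform(0, 2, 500) for i in range(5)})
        mask = rng.random(m.shape) < 0.05
        m = m.mask(mask)
        out = impute_missing_dosages(m)
        np.testing.assert_allclose(
            out.mean().to_numpy(), m.mean().to_numpy(), atol=1e-12
        )
        # observed entries untouched
        obs = ~m.isna()
        assert (out[obs] == m[obs]).all().all() or np.allclose(
            out.to_numpy()[obs.to_numpy()], m.to_numpy()[obs.to_numpy()]
        )


# --------------------------------------------------------------------------
# readers


def _write_fixture_vcf(path, panel, dosages, flip_rsids=()):
    """Hand-written VCF; flip_rsids store the panel's *other* allele as ALT."""
    table = panel.table.set_index("rsid")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dosages.index),
    ]
    for rsid in dosages.columns:
        row = table.loc[rsid]
        if rsid in flip_rsids:
            ref, alt = row["effect_allele"], row["other_allele"]
            ds = 2.0 - dosages[rsid]
        else:
            ref, alt = row["other_allele"], row["effect_allele"]
            ds = dosages[rsid]
        entries = "\t".join("." if np.isnan(d) else f"{d:.4f}" for d in ds)
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tDS\t{entries}"
        )
    path.write_text("\n".join(lines) + "\n")


class TestReadDosages:
    def test_fixture_values_and_shape(self, tmp_path, panel, rng):
        dosages = pd.DataFrame(
            rng.uniform(0, 2, (3, 5)).round(4),
            index=["a", "b", "c"],
            columns=panel.rsids,
        )
        vcf = tmp_path / "fix.vcf"
        _write_fixture_vcf(vcf, panel, dosages)
        result = read_dosages(vcf, panel)
        assert result.absent == []
        assert result.dosages.shape == (3, 5)
        np.testing.assert_allclose(
            result.dosages.to_numpy(), dosages.to_numpy(), atol=1e-3
        )

    def test_orientation_flip(self, tmp_path, panel):
        dosages = pd.DataFrame(
            [[1.3] * 5], index=["s1"], columns=panel.rsids
        )
        vcf = tmp_path / "flip.vcf"
        _write_fixture_vcf(vcf, panel, dosages, flip_rsids={panel.rsids[0]})
        result = read_dosages(vcf, panel)
        # stored file dosage was 0.7 with swapped alleles; reader restores 1.3
        assert result.dosages.loc["s1", panel.rsids[0]] == pytest.approx(1.3, abs=1e-3)
        assert result.dosages.loc["s1", panel.rsids[1]] == pytest.approx(1.3, abs=1e-3)

    def test_allele_mismatch_names_snp(self, tmp_path, panel):
        table = panel.table.copy()
        bad = panel.rsids[2]
        table.loc[table.rsid == bad, ["effect_allele", "other_allele"]] = ["A", "C"]
        wrong_panel = SNPPanel(table)
        dosages = pd.DataFrame([[1.0] * 5], index=["s1"], columns=panel.rsids)
        vcf = tmp_path / "bad.vcf"
        _write_fixture_vcf(vcf, panel, dosages)
        with pytest.raises(DosageReadError, match=bad):
            read_dosages(vcf, wrong_panel)

    def test_absent_snp_reported(self, tmp_path, panel, rng):
        dosages = pd.DataFrame(
            rng.uniform(0, 2, (2, 4)), index=["a", "b"], columns=panel.rsids[:4]
        )
        vcf = tmp_path / "partial.vcf"
        _write_fixture_vcf(vcf, panel, dosages)
        result = read_dosages(vcf, panel)
        assert result.absent == [panel.rsids[4]]

    def test_delimited_table(self, tmp_path, panel, rng):
        dosages = pd.DataFrame(
            rng.uniform(0, 2, (4, 5)), columns=panel.rsids,
            index=pd.Index(["a", "b", "c", "d"], name="sample_id"),
        )
        path = tmp_path / "dosages.tsv"
        dosages.to_csv(path, sep="\t")
        result = read_dosages(path, panel)
        np.testing.assert_allclose(result.dosages.to_numpy(), dosages.to_numpy())

    def test_orientation_invariance_of_prs(self, tmp_path, panel, rng):
        """Scores are identical whether the file stores effect or other allele."""
        from gdmprs.prs import compute_prs

        dosages = pd.DataFrame(
            rng.uniform(0, 2, (6, 5)).round(4), columns=panel.rsids,
            index=[f"s{i}" for i in range(6)],
        )
        v1, v2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_fixture_vcf(v1, panel, dosages)
        _write_fixture_vcf(v2, panel, dosages, flip_rsids=set(panel.rsids[:3]))
        s1 = compute_prs(read_dosages(v1, panel).dosages, panel)
        s2 = compute_prs(read_dosages(v2, panel).dosages, panel)
        np.testing.assert_allclose(
            s1["raw_score"], s2["raw_score"], atol=1e-3
        )
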