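"""Variant preparation, kinship, the mixed model against a GLS oracle,
permutation thresholds, genomic control, linkage-group conflation and
local/distant classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pantrx.datatypes import GenotypeMatrix
from pantrx.eqtl import (
    LmmContext,
    classify_eqtls,
    conflate_linkage_groups,
    genomic_control,
    hotspot_summary,
    kinship,
    lmm_assoc,
    permutation_threshold,
    prepare_variants,
)


def _geno(dosages, positions=None, chroms=None, types=None, orfs=None):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    vids = [f"v{i}" for i in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * m,
            "pos": positions if positions is not None else np.arange(m) * 1000 + 30_000,
            "type": types if types is not None else ["SNP"] * m,
            "orf": orfs if orfs is not None else [None] * m,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    values = pd.DataFrame(dosages, index=vids, columns=[f"i{j}" for j in range(n)])
    return GenotypeMatrix(meta, values)


def _random_geno(rng, m=12, n=30, p=0.4):
    return _geno(rng.binomial(2, p, size=(m, n)))


class TestPrepareVariants:
    def test_mask_and_maf_boundaries(self):
        # 4 isolates -> 8 alleles; dosage sums give exact MAFs
        dosages = [
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # MAF 0.05 -> removed (strict)
            [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # MAF 0.10 -> kept
            [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # subtelomeric SNP -> removed
            [2, 2, 1, 1, 0, 0, 0, 0, 0, 0],  # CNV-type at subtelomere -> kept
        ]
        geno = _geno(
            dosages,
            positions=[50_000, 50_500, 15_000, 15_000],
            types=["SNP", "SNP", "SNP", "CNV"],
        )
        out = prepare_variants(geno, {"chr1": 100_000}, maf_min=0.05, snp_mask=True)
        assert list(out.variant_ids) == ["v1", "v3"]

    def test_mask_skipped_when_disabled(self):
        geno = _geno([[1, 1, 0, 0, 1, 0, 1, 0, 1, 0]], positions=[15_000])
        out = prepare_variants(geno, {"chr1": 100_000}, snp_mask=False)
        assert len(out.variant_ids) == 1

    def test_unknown_chromosome_rejected(self):
        geno = _geno([[1, 0, 1, 0]], chroms=["chrX"])
        with pytest.raises(ValueError, match="unknown chromosome"):
            prepare_variants(geno, {"chr1": 1_000_000})


class TestKinship:
    def test_identical_isolates_match_diagonal(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(50, 10)).astype(float)
        dos[:, 1] = dos[:, 0]  # isolate 1 clones isolate 0
        K = kinship(_geno(dos))
        assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0])
        assert K.iloc[0, 1] == pytest.approx(K.iloc[1, 1])

    def test_independent_genotypes_have_null_off_diagonal(self):
        rng = np.random.default_rng(1)
        n = 40
        K = kinship(_geno(rng.binomial(2, 0.5, size=(400, n))))
        off = K.to_numpy()[np.triu_indices(n, 1)]
        # per-variant centring fixes the mean at -1/(n-1); no relatedness
        # signal beyond that structural offset
        se = off.std() / np.sqrt(len(off))
        assert abs(off.mean() - (-1 / (n - 1))) < 3 * se
        assert abs(off.mean()) < 0.05

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        K = kinship(_geno(rng.binomial(2, 0.3, size=(100, 25))))
        assert np.linalg.eigvalsh(K.to_numpy()).min() >= -1e-8


class TestLmmAssoc:
    def test_matches_naive_gls_oracle(self):
        rng = np.random.default_rng(3)
        geno = _random_geno(rng, m=12, n=30)
        K = kinship(geno)
        n = 30
        dos = geno.values.to_numpy()
        x0 = (dos[0] - dos[0].mean()) / dos[0].std()
        y = pd.Series(rng.normal(size=n) + 0.8 * x0, index=geno.isolate_ids)
        res = lmm_assoc(y, geno, K)
        delta = res.attrs["delta"]
        V = K.to_numpy() + delta * np.eye(n)
        Vi = np.linalg.inv(V)
        for i, vid in enumerate(geno.variant_ids):
            x = (dos[i] - dos[i].mean()) / dos[i].std()
            X = np.column_stack([np.ones(n), x])
            XtVi = X.T @ Vi
            beta = np.linalg.solve(XtVi @ X, XtVi @ y.to_numpy())
            r = y.to_numpy() - X @ beta
            s2 = (r @ Vi @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(XtVi @ X)[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
            assert res.loc[vid, "beta"] == pytest.approx(beta[1], abs=1e-6)
            assert res.loc[vid, "p_raw"] == pytest.approx(p, abs=1e-6)

    def test_identity_kinship_reduces_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        geno = _random_geno(rng, m=5, n=40)
        iso = geno.isolate_ids
        K = pd.DataFrame(np.eye(40), index=iso, columns=iso)
        y = pd.Series(rng.normal(size=40), index=iso)
        res = lmm_assoc(y, geno, K, delta=1e9)  # variance ratio -> pure noise
        dos = geno.values.to_numpy()
        for i, vid in enumerate(geno.variant_ids):
            x = (dos[i] - dos[i].mean()) / dos[i].std()
            ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
            assert res.loc[vid, "p_raw"] == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_zero_variance_trait_rejected(self):
        rng = np.random.default_rng(5)
        geno = _random_geno(rng)
        K = kinship(geno)
        y = pd.Series(1.0, index=geno.isolate_ids)
        with pytest.raises(ValueError, match="zero variance"):
            lmm_assoc(y, geno, K)

    def test_monomorphic_variant_gets_nan(self):
        rng = np.random.default_rng(6)
        dos = rng.binomial(2, 0.4, size=(4, 30)).astype(float)
        dos[2] = 1.0
        geno = _geno(dos)
        K = kinship(geno)
        y = pd.Series(rng.normal(size=30), index=geno.isolate_ids)
        res = lmm_assoc(y, geno, K)
        assert np.isnan(res.loc["v2", "p_raw"])


class TestPermutationThreshold:
    def test_threshold_is_fifth_order_statistic(self):
        rng = np.random.default_rng(7)
        geno = _random_geno(rng, m=30, n=40)
        K = kinship(geno)
        y = pd.Series(rng.normal(size=40), index=geno.isolate_ids)
        threshold, minima = permutation_threshold(
            y, geno, K, n_perm=100, rng=1, return_minima=True
        )
        assert threshold == np.sort(minima)[4]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        geno = _random_geno(rng, m=20, n=30)
        K = kinship(geno)
        y = pd.Series(rng.normal(size=30), index=geno.isolate_ids)
        t1 = permutation_threshold(y, geno, K, n_perm=30, rng=5)
        t2 = permutation_threshold(y, geno, K, n_perm=30, rng=5)
        assert t1 == t2

    def test_too_few_permutations_refused(self):
        rng = np.random.default_rng(9)
        geno = _random_geno(rng)
        K = kinship(geno)
        y = pd.Series(rng.normal(size=30), index=geno.isolate_ids)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(y, geno, K, n_perm=10)


class TestGenomicControl:
    def test_uniform_p_left_unchanged(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=10_000)
        lam, corrected = genomic_control(p)
        assert 0.95 < lam < 1.05
        if lam <= 1:
            np.testing.assert_array_equal(corrected, p)

    def test_doubled_chi2_deflated_to_half_median(self):
        chi = stats.chi2.rvs(1, size=10_000, random_state=11) * 2
        p = stats.chi2.sf(chi, 1)
        lam, corrected = genomic_control(p)
        assert lam == pytest.approx(2.0, rel=0.05)
        assert np.median(corrected) == pytest.approx(0.5, abs=0.02)

    def test_deflation_below_one_left_alone(self):
        chi = stats.chi2.rvs(1, size=5_000, random_state=12) * 0.8
        p = stats.chi2.sf(chi, 1)
        lam, corrected = genomic_control(p)
        assert lam < 1
        np.testing.assert_array_equal(corrected, p)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "p_raw", "p_corrected"]
    )


class TestConflation:
    def test_perfectly_linked_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(13)
        a = rng.binomial(2, 0.5, 40).astype(float)
        geno = _geno([a, a, rng.binomial(2, 0.5, 40)])
        recs = _records(
            [("v0", "g", 1e-8, 1e-8), ("v1", "g", 1e-6, 1e-6), ("v2", "g", 1e-7, 1e-7)]
        )
        out = conflate_linkage_groups(recs, geno)
        reps = out[out["is_group_representative"]]
        assert set(reps["variant_id"]) == {"v0", "v2"}
        assert out["linkage_group"].nunique() == 2

    def test_unlinked_variants_stay_separate(self):
        rng = np.random.default_rng(14)
        geno = _geno(rng.binomial(2, 0.5, size=(2, 200)))
        recs = _records([("v0", "g", 1e-8, 1e-8), ("v1", "g", 1e-6, 1e-6)])
        out = conflate_linkage_groups(recs, geno)
        assert out["is_group_representative"].all()

    def test_transitive_chain_forms_single_group(self):
        rng = np.random.default_rng(15)
        n = 600
        a = rng.binomial(1, 0.5, n).astype(float)
        flip1 = rng.random(n) < 0.08
        b = np.where(flip1, 1 - a, a)
        flip2 = rng.random(n) < 0.08
        c = np.where(flip2, 1 - b, b)
        r2_ab = np.corrcoef(a, b)[0, 1] ** 2
        r2_bc = np.corrcoef(b, c)[0, 1] ** 2
        r2_ac = np.corrcoef(a, c)[0, 1] ** 2
        assert r2_ab > 0.6 and r2_bc > 0.6 and r2_ac < 0.6
        geno = _geno([a, b, c])
        recs = _records(
            [("v0", "g", 1e-8, 1e-8), ("v1", "g", 1e-7, 1e-7), ("v2", "g", 1e-6, 1e-6)]
        )
        out = conflate_linkage_groups(recs, geno)
        assert out["linkage_group"].nunique() == 1
        assert out["is_group_representative"].sum() == 1

    def test_conflation_never_increases_records(self):
        rng = np.random.default_rng(16)
        geno = _random_geno(rng, m=6, n=50)
        recs = _records(
            [(f"v{i}", "g", 10.0 ** -(i + 3), 10.0 ** -(i + 3)) for i in range(6)]
        )
        out = conflate_linkage_groups(recs, geno)
        assert len(out) == len(recs)
        assert out["is_group_representative"].sum() <= len(recs)


class TestClassification:
    annotation = pd.DataFrame(
        {
            "class": ["core"],
            "chrom": ["chr1"],
            "start": [100_000],
            "end": [102_000],
            "length": [2_000],
        },
        index=pd.Index(["gene1"], name="gene_id"),
    )

    def test_snp_window_and_cnv_orf_rules(self):
        geno = _geno(
            [[0, 1, 2, 0], [0, 1, 2, 0], [1, 2, 1, 2], [1, 2, 1, 2]],
            positions=[90_000, 132_001, 101_000, 101_000],
            chroms=["chr1", "chr1", "chr1", "chr1"],
            types=["SNP", "SNP", "CNV", "CNV"],
            orfs=[None, None, "gene1", "neighbour"],
        )
        recs = pd.DataFrame(
            {
                "variant_id": ["v0", "v1", "v2", "v3"],
                "gene_id": ["gene1"] * 4,
                "p_corrected": [1e-8] * 4,
            }
        )
        out = classify_eqtls(recs, self.annotation, geno)
        assert out["locality"].tolist() == ["local", "distant", "local", "distant"]

    def test_missing_gene_coordinates_give_unknown(self):
        geno = _geno([[0, 1, 2, 0]], positions=[90_000])
        recs = pd.DataFrame(
            {"variant_id": ["v0"], "gene_id": ["ghost"], "p_corrected": [1e-8]}
        )
        out = classify_eqtls(recs, self.annotation, geno)
        assert out["locality"].tolist() == ["unknown"]


class TestHotspots:
    def test_pleiotropic_variant_tops_list_and_counts_conserve(self):
        recs = pd.DataFrame(
            {
                "variant_id": ["hot"] * 5 + ["v1", "v2"],
                "gene_id": [f"g{i}" for i in range(5)] + ["g5", "g6"],
                "is_group_representative": True,
            }
        )
        counts, singleton_fraction = hotspot_summary(recs)
        assert counts.iloc[0]["variant_id"] == "hot"
        assert counts.iloc[0]["n_traits"] == 5
        assert counts["n_traits"].sum() == len(recs)
        assert singleton_fraction == pytest.approx(2 / 3)
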