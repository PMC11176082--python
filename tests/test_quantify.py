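"""TPM closed forms, filtering/merging bookkeeping, VST properties,
sample-identity ranking and the aneuploid dosage-response statistic."""

import numpy as np
import pandas as pd
import pytest

from pantrx.datatypes import ExpressionMatrix, log2_tpm1
from pantrx.quantify import (
    compute_tpm,
    dosage_response,
    filter_and_merge_genes,
    validate_sample_identity,
    variance_stabilize,
)
from pantrx.simulate import SimConfig, karyotype_table, simulate_population

from conftest import random_count_matrix


def _em(array, genes=None, isolates=None, scale="raw_count"):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    isolates = isolates or [f"s{j}" for j in range(array.shape[1])]
    return ExpressionMatrix(pd.DataFrame(array, index=genes, columns=isolates), scale)


class TestComputeTpm:
    def test_closed_form(self):
        counts = _em([[10], [40]])
        tpm = compute_tpm(counts, pd.Series([1000, 2000], index=["g0", "g1"]))
        np.testing.assert_allclose(
            tpm.values.iloc[:, 0], [1e6 / 3, 2e6 / 3], rtol=1e-9
        )

    def test_symmetry_equal_counts_equal_lengths(self):
        counts = _em(np.full((4, 2), 7))
        tpm = compute_tpm(counts, pd.Series(1500, index=counts.gene_ids))
        assert (tpm.values.to_numpy() == 250000).all()

    def test_all_zero_column_stays_zero(self):
        counts = _em([[5, 0], [3, 0]])
        tpm = compute_tpm(counts, pd.Series([100, 200], index=["g0", "g1"]))
        assert (tpm.values.iloc[:, 1] == 0).all()
        assert tpm.values.iloc[:, 0].sum() == pytest.approx(1e6)

    def test_missing_length_raises(self):
        counts = _em([[1], [2]])
        with pytest.raises(ValueError, match="missing gene lengths"):
            compute_tpm(counts, pd.Series([100.0], index=["g0"]))


def _annotation(gene_ids, homolog=None, cls="core"):
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "class": [cls] * n,
            "subcategory": ["none"] * n,
            "chrom": ["chr1"] * n,
            "start": np.arange(1, n + 1) * 1000,
            "end": np.arange(1, n + 1) * 1000 + 500,
            "strand": ["+"] * n,
            "length": [500] * n,
            "homolog_of": homolog if homolog is not None else [None] * n,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


class TestFilterAndMerge:
    def test_identity_when_nothing_to_do(self):
        rng = np.random.default_rng(0)
        counts = random_count_matrix(rng, n_genes=10, mean=500)
        tpm = compute_tpm(counts, pd.Series(1000, index=counts.gene_ids))
        out, report = filter_and_merge_genes(tpm, _annotation(list(counts.gene_ids)))
        assert report.n_low_expression_filtered == 0
        assert report.n_merged == 0
        pd.testing.assert_frame_equal(out.values, tpm.values)

    def test_matches_brute_force_filter_on_random_matrix(self):
        rng = np.random.default_rng(1)
        # half the genes hover near the log2(TPM+1) = 1 boundary once a
        # high-count sink gene dominates the library
        counts = rng.poisson(np.where(rng.random((50, 8)) < 0.5, 1, 300))
        counts = np.vstack([counts, np.full((1, 8), 10_000_000)])
        em = _em(counts)
        tpm = compute_tpm(em, pd.Series(1000, index=em.gene_ids))
        out, _ = filter_and_merge_genes(tpm, _annotation(list(em.gene_ids)))
        log2v = np.log2(tpm.values + 1)
        expected = [
            g
            for g in tpm.gene_ids
            if (log2v.loc[g] < 1).sum() / tpm.n_isolates < 0.5
        ]
        assert list(out.gene_ids) == expected

    def test_homolog_merge_sums_and_drops(self):
        tpm_raw = _em([[100.0, 100.0], [300.0, 300.0], [600.0, 600.0]], scale="raw_count")
        tpm = compute_tpm(tpm_raw, pd.Series(1000, index=tpm_raw.gene_ids))
        ann = _annotation(["g0", "g1", "g2"], homolog=[None, None, "g0"])
        out, report = filter_and_merge_genes(tpm, ann)
        assert report.n_merged == 1
        assert "g2" not in out.gene_ids
        # g0 now carries (100+600)/1000 of each column's mass
        assert out.values.loc["g0"].iloc[0] == pytest.approx(0.7 * 1e6)

    def test_homolog_cycle_raises(self):
        counts = _em([[10.0], [10.0]])
        tpm = compute_tpm(counts, pd.Series(100, index=counts.gene_ids))
        ann = _annotation(["g0", "g1"], homolog=["g1", "g0"])
        with pytest.raises(ValueError, match="cycle"):
            filter_and_merge_genes(tpm, ann)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(np.where(rng.random((30, 6)) < 0.4, 1, 200))
        counts = np.vstack([counts, np.full((1, 6), 10_000_000)])
        em = _em(counts)
        tpm = compute_tpm(em, pd.Series(1000, index=em.gene_ids))
        once, _ = filter_and_merge_genes(tpm, _annotation(list(em.gene_ids)))
        twice, rep2 = filter_and_merge_genes(once, _annotation(list(once.gene_ids)))
        assert rep2.n_low_expression_filtered == 0
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_column_sums_recomputed_to_million(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(np.where(rng.random((30, 6)) < 0.4, 1, 200))
        em = _em(counts)
        tpm = compute_tpm(em, pd.Series(1000, index=em.gene_ids))
        out, _ = filter_and_merge_genes(tpm, _annotation(list(em.gene_ids)))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-9)


class TestVarianceStabilize:
    def test_proportional_columns_agree_after_normalization(self):
        base = np.array([10, 200, 3000, 50, 400, 800, 25, 90, 1500, 60])
        em = _em(np.column_stack([base, base * 2]))
        vst = variance_stabilize(em)
        np.testing.assert_allclose(
            vst.values.iloc[:, 0], vst.values.iloc[:, 1], atol=1e-6
        )

    def test_decile_variance_flat_on_nb_counts(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.uniform(np.log(10), np.log(10000), 600))
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(600, 80))
        em = _em(counts)
        ones = pd.Series(1.0, index=em.isolate_ids)
        vst = variance_stabilize(em, size_factors=ones)
        deciles = pd.qcut(pd.Series(mu, index=em.gene_ids), 10, labels=False)
        vst_ratio = (
            vst.values.var(axis=1).groupby(deciles).mean().agg(lambda s: s.max() / s.min())
        )
        raw_ratio = (
            em.values.var(axis=1).groupby(deciles).mean().agg(lambda s: s.max() / s.min())
        )
        assert vst_ratio < 2
        assert raw_ratio > 10

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(8)
        filler = rng.poisson(100, size=(20, 30))
        ladder = np.arange(30)[None, :]  # one gene sweeping 0..29
        em = _em(np.vstack([ladder, filler]))
        ones = pd.Series(1.0, index=em.isolate_ids)
        vst = variance_stabilize(em, size_factors=ones, min_expressed_fraction=1.0)
        row = vst.values.iloc[0].to_numpy()
        assert (np.diff(row) > 0).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            variance_stabilize(_em(np.zeros((3, 4), dtype=int)))


class TestSampleIdentity:
    panel = {
        "strainA": {f"v{i}" for i in range(60)},
        "strainB": {f"v{i}" for i in range(55, 65)},
        "strainC": {"x1", "x2"},
        "strainD": {"y1"},
    }

    def test_clear_match_is_validated(self):
        sample = {f"v{i}" for i in range(50)}
        ranking, verdict = validate_sample_identity(sample, self.panel, "strainA")
        assert verdict == "validated"
        assert ranking.iloc[0]["strain"] == "strainA"
        assert ranking.iloc[0]["shared_rare_snps"] == 50

    def test_expected_out_of_top3_is_reassign_candidate(self):
        panel = {
            "s1": set(range(100)),
            "s2": set(range(40)),
            "s3": set(range(30)),
            "s4": set(range(20)),
            "expected": {999},
        }
        sample = set(range(100)) | {999}
        ranking, verdict = validate_sample_identity(sample, panel, "expected")
        assert verdict == "reassign_candidate"
        assert ranking.iloc[0]["strain"] == "s1"

    def test_no_shared_variants_is_unresolved(self):
        _, verdict = validate_sample_identity({"zzz"}, self.panel, "strainA")
        assert verdict == "unresolved"

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError):
            validate_sample_identity({"v1"}, {}, "strainA")

    def test_invariant_to_panel_order(self):
        sample = {f"v{i}" for i in range(50)}
        items = list(self.panel.items())
        r1, v1 = validate_sample_identity(sample, dict(items), "strainA")
        r2, v2 = validate_sample_identity(sample, dict(reversed(items)), "strainA")
        assert v1 == v2
        pd.testing.assert_frame_equal(r1, r2)


class TestDosageResponse:
    @pytest.mark.parametrize("dc,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_attenuation_recovers_compensation(self, dc, expected):
        ds = simulate_population(
            SimConfig(seed=2, dosage_compensation=dc, n_aneuploid_isolates=10)
        )
        expr = log2_tpm1(compute_tpm(ds.counts, ds.gene_annotation["length"]))
        dr = dosage_response(
            expr,
            karyotype_table(ds),
            ds.isolate_annotation["ploidy"],
            ds.gene_annotation["chrom"],
        )
        assert len(dr) == 10
        assert dr["attenuation"].mean() == pytest.approx(expected, abs=0.1)

    def test_uncompensated_trisomy_ratio_near_1_5(self):
        ds = simulate_population(
            SimConfig(seed=4, dosage_compensation=0.0, n_aneuploid_isolates=8)
        )
        expr = log2_tpm1(compute_tpm(ds.counts, ds.gene_annotation["length"]))
        dr = dosage_response(
            expr,
            karyotype_table(ds),
            ds.isolate_annotation["ploidy"],
            ds.gene_annotation["chrom"],
        )
        assert dr["expected_ratio"].unique() == pytest.approx([1.5])
        assert dr["observed_ratio"].mean() == pytest.approx(1.5, abs=0.1)
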