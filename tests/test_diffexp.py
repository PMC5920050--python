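import numpy as np
import pandas as pd
import pytest

from lncmm import diffexp as de
from lncmm import expression as ex


def nb_matrix(rng, n_genes=100, n_samples=6, mean=100.0, alpha=0.2):
    r = 1.0 / alpha
    vals = rng.negative_binomial(r, r / (r + mean), size=(n_genes, n_samples))
    return ex.CountMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{i}" for i in range(n_samples)])
    )


def split_contrast(m, n_pos, name="x"):
    ids = m.sample_ids
    return de.Contrast(name, frozenset(ids[:n_pos]), frozenset(ids[n_pos:]))


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        df = pd.DataFrame({"a": [5, 10, 2], "b": [5, 10, 2], "c": [5, 10, 2]},
                          index=["g1", "g2", "g3"])
        f = de.size_factors(ex.CountMatrix(df))
        np.testing.assert_allclose(f, 1.0)

    def test_doubled_column_has_double_factor(self):
        rng = np.random.default_rng(1)
        m = nb_matrix(rng, 200, 4)
        df = m.counts.copy()
        df["dup"] = df["s0"]
        df["dup2"] = df["s0"] * 2
        f = de.size_factors(ex.CountMatrix(df))
        assert f["dup2"] == pytest.approx(2 * f["dup"], rel=1e-12)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(2)
        m = nb_matrix(rng, 100, 6)
        got = de.size_factors(m).to_numpy()
        # independent brute-force: per-sample median of counts/geomean over
        # genes positive everywhere, then rescale to geometric mean 1
        vals = m.counts.to_numpy(dtype=float)
        rows = [g for g in vals if (g > 0).all()]
        raw = []
        for s in range(6):
            ratios = sorted(
                g[s] / np.prod(g) ** (1 / len(g)) for g in rows
            )
            raw.append(np.median(ratios))
        raw = np.array(raw)
        expect = raw / np.prod(raw) ** (1 / 6)
        np.testing.assert_allclose(got, expect, atol=1e-12, rtol=1e-12)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(3)
        m = nb_matrix(rng, 100, 5)
        f1 = de.size_factors(m)
        f2 = de.size_factors(ex.CountMatrix(m.counts * 7))
        np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_no_common_positive_gene_errors(self):
        df = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="positive"):
            de.size_factors(ex.CountMatrix(df))


class TestDispersion:
    def test_poisson_limit_small(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(500.0, size=(2000, 30))
        m = ex.CountMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(2000)],
                         columns=[f"s{i}" for i in range(30)])
        )
        disp = de.estimate_dispersion(m, split_contrast(m, 8))
        assert float(np.median(disp)) < 0.05

    def test_constant_gene_zero(self):
        df = pd.DataFrame(np.full((3, 6), 7), index=["g1", "g2", "g3"],
                          columns=[f"s{i}" for i in range(6)])
        m = ex.CountMatrix(df)
        disp = de.estimate_dispersion(m, split_contrast(m, 3))
        np.testing.assert_allclose(disp, 0.0)

    def test_parameter_recovery(self):
        medians = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            m = nb_matrix(rng, 500, 30, mean=100.0, alpha=0.2)
            disp = de.estimate_dispersion(m, split_contrast(m, 8))
            medians.append(float(np.median(disp)))
        assert 0.1 <= float(np.median(medians)) <= 0.3

    def test_one_sample_side_rejected(self):
        rng = np.random.default_rng(5)
        m = nb_matrix(rng, 20, 4)
        with pytest.raises(ValueError, match="2 samples"):
            de.estimate_dispersion(m, split_contrast(m, 1))


class TestWald:
    def test_antisymmetric_under_side_swap(self):
        rng = np.random.default_rng(6)
        m = nb_matrix(rng, 200, 10)
        c = split_contrast(m, 4)
        swapped = de.Contrast("x", c.negative_samples, c.positive_samples)
        f = de.size_factors(m)
        disp = de.estimate_dispersion(m, c, f)
        t1 = de.nb_wald_test(m, c, f, disp)
        t2 = de.nb_wald_test(m, swapped, f, disp)
        np.testing.assert_allclose(
            t1.log2_fold_change, -t2.log2_fold_change, atol=1e-10
        )
        np.testing.assert_allclose(t1.wald_stat, -t2.wald_stat, atol=1e-10)
        np.testing.assert_allclose(t1.p_value, t2.p_value, atol=1e-12)

    def test_all_zero_gene_gets_p_one(self):
        rng = np.random.default_rng(7)
        m = nb_matrix(rng, 50, 10)
        df = m.counts.copy()
        df.loc["gz"] = 0
        m2 = ex.CountMatrix(df)
        tab = de.nb_wald_test(m2, split_contrast(m2, 4))
        assert tab.loc["gz", "p_value"] == 1.0
        assert tab.loc["gz", "log2_fold_change"] == 0.0

    def test_planted_fold_change_detected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(300 + seed)
            m = nb_matrix(rng, 200, 30, mean=100.0, alpha=0.05)
            df = m.counts.copy()
            # plant a 4-fold increase for the first 8 samples on one gene
            r = 1 / 0.05
            df.loc["g0", df.columns[:8]] = rng.negative_binomial(
                r, r / (r + 400.0), size=8
            )
            m2 = ex.CountMatrix(df)
            tab = de.nb_wald_test(m2, split_contrast(m2, 8))
            if tab.loc["g0", "p_value"] < 1e-3:
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeds


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(de.bh_adjust([0.03]), [0.03])

    def test_hand_worked_stepup(self):
        q = de.bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.05] * 5)

    def test_all_equal(self):
        np.testing.assert_allclose(de.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(8)
        p = rng.random(500)
        q = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_stepup_properties_hold_for_arbitrary_p(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=200)
        @given(
            st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=50)
        )
        def check(p):
            q = de.bh_adjust(p)
            assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-15).all()

        check()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(1000) ** 2
        q = de.bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-12)


class TestSignatures:
    def test_empty_results(self):
        sigs = de.build_signatures({"c1": pd.DataFrame()})
        assert sigs[0].up == [] and sigs[0].down == []

    def test_union_of_overlapping_signatures(self):
        a = de.DESignature("A", up=[f"g{i}" for i in range(10)])
        b = de.DESignature("B", up=[f"g{i}" for i in range(5, 20)])
        union = de.signature_union([a, b])
        assert len(union) == 20

    def test_direction_consistency(self, default_dataset):
        ds = default_dataset
        lnc_ids = [r.gene_id for r in ds.annotation if r.is_lncRNA]
        lnc = ex.filter_expressed(ds.counts.subset_genes(lnc_ids))
        c = [c for c in de.contrasts_from_cohort(ds.cohort) if c.name == "HD"][0]
        res = de.NBDifferential(lnc, c).fit(fdr=0.01)
        sig = res.signature
        assert not (set(sig.up) & set(sig.down))
        tab = res.table
        assert (tab.loc[sig.up, "log2_fold_change"] > 0).all()
        assert (tab.loc[sig.up, "q_value"] < 0.01).all()
        assert (tab.loc[sig.down, "log2_fold_change"] < 0).all()


class TestContrastsAndModel:
    def test_small_groups_excluded(self, default_dataset):
        names = {c.name for c in de.contrasts_from_cohort(default_dataset.cohort)}
        # features with fewer than 3 positive samples are dropped
        assert "P53" not in names and "FAM46C" not in names
        assert {"HD", "t(11;14)", "t(4;14)", "MAF-trx", "del(17)", "MAPK"} <= names

    def test_na_samples_excluded_from_both_sides(self, default_dataset):
        cohort = default_dataset.cohort
        c = [c for c in de.contrasts_from_cohort(cohort) if c.name == "HD"][0]
        na = set(cohort.index[cohort["HD"] == "NA"])
        assert len(na) == 2
        assert not (na & c.used_samples)

    def test_model_refuses_tiny_group(self, default_dataset):
        ds = default_dataset
        lnc_ids = [r.gene_id for r in ds.annotation if r.is_lncRNA]
        lnc = ex.filter_expressed(ds.counts.subset_genes(lnc_ids))
        tiny = de.Contrast(
            "tiny",
            frozenset(lnc.sample_ids[:2]),
            frozenset(lnc.sample_ids[2:]),
        )
        with pytest.raises(ValueError, match="minimum"):
            de.NBDifferential(lnc, tiny)

    def test_summary_mentions_contrast_and_counts(self, default_dataset):
        ds = default_dataset
        lnc_ids = [r.gene_id for r in ds.annotation if r.is_lncRNA]
        lnc = ex.filter_expressed(ds.counts.subset_genes(lnc_ids))
        c = [c for c in de.contrasts_from_cohort(ds.cohort) if c.name == "HD"][0]
        res = de.NBDifferential(lnc, c).fit()
        text = res.summary()
        assert "HD" in text and "FDR" in text and "up" in text
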