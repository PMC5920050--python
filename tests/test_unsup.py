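import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from lncmm import unsup


def make_expr(rng, n_genes=50, n_samples=8):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestTopVariable:
    def test_saturates_at_gene_count(self):
        rng = np.random.default_rng(0)
        m = np.abs(make_expr(rng, 10)) + 1
        assert len(unsup.top_variable(m, 100)) == 10

    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(1)
        m = np.abs(make_expr(rng, 10)) + 1
        m.loc["flat"] = 5.0
        assert unsup.top_variable(m, 11)[-1] == "flat"

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        m = np.abs(make_expr(rng, 200, 30)) + 0.1
        got = unsup.top_variable(m, 50)
        cv = (m.std(axis=1, ddof=1) / m.mean(axis=1)).to_dict()
        expect = sorted(m.index, key=lambda g: (-cv[g], g))[:50]
        assert got == expect

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            unsup.top_variable(pd.DataFrame({"a": [1.0]}), 0)


def brute_force_merges(dist, linkage):
    """Independent agglomeration oracle: clusters as explicit leaf sets,
    linkage distance recomputed from the original matrix each step."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                cross = [dist[i, j] for i in clusters[a] for j in clusters[b]]
                if linkage == "average":
                    d = float(np.mean(cross))
                elif linkage == "single":
                    d = float(np.min(cross))
                else:
                    d = float(np.max(cross))
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


class TestHclust:
    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(3)
        m = make_expr(rng, 60, 6)
        m["s5"] = m["s0"]  # exact duplicate, distance 0
        den = unsup.hclust_pearson(m, linkage="average")
        a, b, h, _ = den.merges[0]
        assert {den.leaf_ids[a], den.leaf_ids[b]} == {"s0", "s5"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_groups_recovered(self):
        rng = np.random.default_rng(4)
        base1, base2 = rng.normal(size=50), rng.normal(size=50)
        cols = {}
        for i in range(4):
            cols[f"a{i}"] = base1 + rng.normal(scale=0.1, size=50)
        for i in range(4):
            cols[f"b{i}"] = -base1 + rng.normal(scale=0.1, size=50)
        m = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
        den = unsup.hclust_pearson(m, linkage="average")
        labels = den.cut(2)
        groups = {}
        for s, lab in labels.items():
            groups.setdefault(lab, set()).add(s)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"a0", "a1", "a2", "a3"}),
            frozenset({"b0", "b1", "b2", "b3"}),
        }

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    def test_merge_sequence_matches_brute_force(self, linkage):
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            m = make_expr(rng, 40, 5)
            dist = unsup.pearson_distance(m).to_numpy()
            den = unsup.hclust_pearson(m, linkage=linkage)
            expect = brute_force_merges(dist, linkage)
            got = [(a, b, h) for a, b, h, _ in den.merges]
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expect):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh, abs=1e-10)

    def test_average_linkage_agrees_with_scipy(self):
        from scipy.cluster import hierarchy as sch
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(60)
        m = make_expr(rng, 80, 12)
        dist = unsup.pearson_distance(m)
        Z = sch.linkage(squareform(dist.to_numpy(), checks=False), "average")
        den = unsup.hclust_pearson(m, linkage="average")
        np.testing.assert_allclose(
            sorted(h for _, _, h, _ in den.merges), sorted(Z[:, 2]), atol=1e-10
        )

    def test_cut_sizes_sum_to_n(self):
        rng = np.random.default_rng(5)
        m = make_expr(rng, 30, 9)
        den = unsup.hclust_pearson(m, linkage="centroid")
        for k in range(1, 10):
            labels = den.cut(k)
            assert len(labels) == 9
            assert len(set(labels.values())) == k

    def test_invariance_gene_order_and_affine(self):
        rng = np.random.default_rng(6)
        m = make_expr(rng, 40, 7)
        den1 = unsup.hclust_pearson(m, linkage="average")
        shuffled = m.sample(frac=1, random_state=1)
        den2 = unsup.hclust_pearson(shuffled, linkage="average")
        rescaled = m * 3.5 + 1.2  # per-sample positive affine transform
        den3 = unsup.hclust_pearson(rescaled, linkage="average")
        for other in (den2, den3):
            # same merge structure; heights equal up to float jitter
            for (a, b, h, s), (oa, ob, oh, os) in zip(den1.merges, other.merges):
                assert (a, b, s) == (oa, ob, os)
                assert h == pytest.approx(oh, abs=1e-9)

    def test_zero_variance_sample_named(self):
        rng = np.random.default_rng(7)
        m = make_expr(rng, 20, 4)
        m["s2"] = 1.0
        with pytest.raises(ValueError, match="s2"):
            unsup.hclust_pearson(m)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(8)
        m = make_expr(rng, 20, 5)
        nwk = unsup.hclust_pearson(m, linkage="average").to_newick()
        assert nwk.endswith(";")
        for s in m.columns:
            assert s in nwk


class TestBranchFisher:
    def test_perfect_separation_closed_form(self):
        """All 8 positives isolated in one 8-sample cluster of 30."""
        partition = {f"s{i}": (0 if i < 8 else 1) for i in range(30)}
        feature = {f"s{i}": ("positive" if i < 8 else "negative") for i in range(30)}
        p = unsup.branch_fisher(partition, feature)
        closed = 1.0 / special.comb(30, 8, exact=True)
        assert p[0] == pytest.approx(closed, rel=1e-10)

    def test_single_cluster_degenerate(self):
        partition = {f"s{i}": 0 for i in range(10)}
        feature = {f"s{i}": ("positive" if i < 4 else "negative") for i in range(10)}
        p = unsup.branch_fisher(partition, feature)
        assert p[0] == pytest.approx(1.0)

    def test_no_positive_feature_warns_p_one(self):
        partition = {"a": 0, "b": 1}
        feature = {"a": "negative", "b": "NA"}
        with pytest.warns(UserWarning, match="no positive"):
            p = unsup.branch_fisher(partition, feature)
        assert set(p.values()) == {1.0}

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(9)
        partition = {f"s{i}": int(rng.integers(0, 3)) for i in range(20)}
        feature = {
            f"s{i}": ("positive" if rng.random() < 0.4 else "negative")
            for i in range(20)
        }
        flipped = {
            s: {"positive": "negative", "negative": "positive"}[v]
            for s, v in feature.items()
        }
        p1 = unsup.branch_fisher(partition, feature)
        p2 = unsup.branch_fisher(partition, flipped)
        for lab in p1:
            assert p1[lab] == pytest.approx(p2[lab], rel=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            perm = rng.permutation(30)
            partition = {f"s{i}": (0 if i < 10 else 1) for i in range(30)}
            feature = {
                f"s{perm[i]}": ("positive" if i < 8 else "negative")
                for i in range(30)
            }
            if unsup.branch_fisher(partition, feature)[0] < 0.05:
                hits += 1
        assert hits / n_rep <= 0.07  # discrete test: at most nominal-ish


class TestMantelHaenszel:
    def test_null_identity(self):
        strata = [np.array([[5, 5], [5, 5]])] * 3
        stat, p = unsup.mantel_haenszel(strata)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_stratum_equals_chi_squared(self):
        stat, p = unsup.mantel_haenszel([np.array([[10, 0], [0, 10]])])
        assert stat == pytest.approx(20.0, rel=1e-12)
        assert p < 1e-4

    def test_zero_margin_stratum_dropped(self):
        good = np.array([[10, 3], [5, 12]])
        bad = np.array([[0, 0], [5, 12]])
        with pytest.warns(UserWarning, match="zero margin"):
            stat, _ = unsup.mantel_haenszel([good, bad])
        stat_only, _ = unsup.mantel_haenszel([good])
        assert stat == pytest.approx(stat_only)
        with pytest.raises(ValueError, match="zero margins"):
            with pytest.warns(UserWarning):
                unsup.mantel_haenszel([bad])

    def test_agrees_with_statsmodels_up_to_variance_convention(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(11)
        # equal-n strata so the Cochran/hypergeometric variance ratio is
        # exactly (n-1)/n
        n = 60
        strata = [
            rng.multinomial(n, [0.3, 0.2, 0.25, 0.25]).reshape(2, 2)
            for _ in range(4)
        ]
        stat, _ = unsup.mantel_haenszel(strata)
        sm_stat = float(
            StratifiedTable(list(strata)).test_null_odds(
                correction=False
            ).statistic
        )
        assert stat == pytest.approx(sm_stat * n / (n - 1), rel=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            strata = []
            for _ in range(3):
                row = rng.multinomial(40, [0.25] * 4)
                strata.append(row.reshape(2, 2))
            try:
                _, p = unsup.mantel_haenszel(strata)
            except ValueError:
                continue
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestAssociate:
    def test_report_structure(self, default_dataset):
        ds = default_dataset
        rng = np.random.default_rng(13)
        m = pd.DataFrame(
            rng.normal(size=(40, 30)),
            index=[f"g{i}" for i in range(40)],
            columns=ds.cohort.index,
        )
        den = unsup.hclust_pearson(m, linkage="average")
        report = unsup.associate_features(den, ds.cohort, k=4)
        assert report.k == 4
        assert set(report.branch_p) == set(ds.cohort.columns)
        assert 0 < report.mh_p <= 1
        d = report.to_dict()
        assert "mantel_haenszel" in d
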