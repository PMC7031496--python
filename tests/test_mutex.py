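"""Binarization, pairwise Fisher exact matrices, gene clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from culprit import (BinaryMatrix, GeneratorConfig, binarize_within_group,
                     cluster_genes, cluster_signatures, generate_pan_tumor,
                     metagene_score, pairwise_fisher, partition_tertiles,
                     restrict_to_low_tertile, synexpression_groups,
                     threshold_mutex_genes)
from culprit.errors import DegenerateInputError
from conftest import make_cohort


def _binary(values, genes=None):
    values = np.atleast_2d(np.asarray(values))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=[f"s{i}" for i in range(values.shape[1])])
    return BinaryMatrix(df, pd.Series("grp", index=df.columns))


class TestBinarize:
    @pytest.mark.parametrize("values,expected", [
        ([3., 3., 3.], [0, 0, 0]),         # constant: nothing strictly above mean
        ([1., 3.], [0, 1]),
        ([1., 2., 3., 6.], [0, 0, 0, 1]),  # mean 3, only 6 above
    ])
    def test_within_group_threshold(self, values, expected):
        cohort = make_cohort([values])
        out = binarize_within_group(cohort)
        assert list(out.values.loc["g0"]) == expected

    def test_groups_binarized_separately_then_concatenated(self):
        cohort = make_cohort([[1., 3., 100., 104.]],
                             groups=["A", "A", "B", "B"])
        out = binarize_within_group(cohort)
        assert list(out.values.loc["g0"]) == [0, 1, 0, 1]

    def test_invariant_to_per_group_affine_rescaling(self, rng):
        vals = rng.uniform(0, 8, size=(6, 12))
        groups = ["A"] * 6 + ["B"] * 6
        base = binarize_within_group(make_cohort(vals, groups=groups))
        scaled = vals.copy()
        scaled[:, :6] = 3.0 * scaled[:, :6] + 1.0
        scaled[:, 6:] = 0.5 * scaled[:, 6:] + 7.0
        rescaled = binarize_within_group(make_cohort(scaled, groups=groups))
        pd.testing.assert_frame_equal(base.values, rescaled.values)


class TestPairwiseFisher:
    def test_independence_gives_zero_log_or(self):
        # joint states: 5 (1,1), 5 (1,0), 5 (0,1), 5 (0,0)
        a = [1] * 10 + [0] * 10
        b = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        mm = pairwise_fisher(_binary([a, b]))
        assert mm.log2_or.loc["g0", "g1"] == pytest.approx(0.0)

    def test_perfect_exclusion_and_cooccurrence(self):
        a = [1] * 10 + [0] * 10
        excl = [0] * 10 + [1] * 10
        cooc = [1] * 10 + [0] * 10
        mm = pairwise_fisher(_binary([a, excl, cooc],
                                     genes=["a", "excl", "cooc"]))
        # Haldane-corrected log2 OR: log2(0.25 / 110.25)
        expected = np.log2(0.25 / 110.25)
        assert mm.log2_or.loc["a", "excl"] == pytest.approx(expected, abs=1e-9)
        assert mm.log2_or.loc["a", "cooc"] == pytest.approx(-expected, abs=1e-9)
        # two-sided p from the hypergeometric enumeration with margins (10,10)
        n, r, k = 20, 10, 10
        xs = np.arange(0, 11)
        pmf = stats.hypergeom.pmf(xs, n, r, k)
        p_exact = pmf[pmf <= pmf[0] * (1 + 1e-12)].sum()
        assert mm.p.loc["a", "excl"] == pytest.approx(p_exact, rel=1e-10)
        assert mm.p.loc["a", "excl"] == pytest.approx(1.08e-5, rel=5e-3)
        assert mm.p.loc["a", "cooc"] == pytest.approx(p_exact, rel=1e-10)

    def test_symmetry_and_relabeling(self, rng):
        vals = rng.integers(0, 2, size=(5, 30))
        vals[:, 0] = 1; vals[:, 1] = 0        # avoid degenerate margins
        mm = pairwise_fisher(_binary(vals))
        np.testing.assert_allclose(mm.log2_or, mm.log2_or.T)
        np.testing.assert_allclose(mm.q, mm.q.T)
        assert np.isnan(np.diag(mm.log2_or)).all()

    def test_flipping_one_gene_negates_its_log_ors(self, rng):
        vals = rng.integers(0, 2, size=(4, 40))
        vals[:, 0] = 1; vals[:, 1] = 0
        mm = pairwise_fisher(_binary(vals))
        flipped = vals.copy()
        flipped[0] = 1 - flipped[0]
        mm_f = pairwise_fisher(_binary(flipped))
        for j in range(1, 4):
            assert mm_f.log2_or.iloc[0, j] == pytest.approx(
                -mm.log2_or.iloc[0, j], abs=1e-9)

    def test_degenerate_gene_flagged_and_excluded_from_q(self):
        a = [1] * 10 + [0] * 10
        dead = [0] * 20
        mm = pairwise_fisher(_binary([a, dead, a], genes=["a", "dead", "b"]))
        assert "dead" in mm.degenerate
        assert np.isnan(mm.q.loc["a", "dead"])
        assert np.isfinite(mm.q.loc["a", "b"])

    def test_two_sided_p_matches_enumeration_small_tables(self, rng):
        """Exhaustive hypergeometric oracle on random small binary data."""
        for _ in range(20):
            n = int(rng.integers(8, 25))
            vals = rng.integers(0, 2, size=(2, n))
            if len(np.unique(vals[0])) < 2 or len(np.unique(vals[1])) < 2:
                continue
            mm = pairwise_fisher(_binary(vals))
            a = int(np.sum((vals[0] == 1) & (vals[1] == 1)))
            r, k = int(vals[0].sum()), int(vals[1].sum())
            lo, hi = max(0, r + k - n), min(r, k)
            xs = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(xs, n, r, k)
            p_exact = min(1.0, pmf[pmf <= stats.hypergeom.pmf(a, n, r, k)
                                   * (1 + 1e-9)].sum())
            assert mm.p.loc["g0", "g1"] == pytest.approx(p_exact, abs=1e-10)


class TestThreshold:
    def test_no_passing_pair_gives_empty_set(self):
        a = [1] * 10 + [0] * 10
        b = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        mm = pairwise_fisher(_binary([a, b]))
        assert threshold_mutex_genes(mm, -1.0, 1e-30) == frozenset()

    def test_single_passing_pair_returns_both_genes(self):
        a = [1] * 10 + [0] * 10
        excl = [0] * 10 + [1] * 10
        indep = [1, 0] * 10
        mm = pairwise_fisher(_binary([a, excl, indep],
                                     genes=["a", "excl", "indep"]))
        out = threshold_mutex_genes(mm, -1.0, 1e-3)
        assert out == frozenset({"a", "excl"})


class TestClustering:
    def test_identical_vectors_merge_at_zero(self, rng):
        v = rng.normal(size=20)
        feats = pd.DataFrame([v, v, rng.normal(size=20)],
                             index=["a", "b", "c"])
        cs = cluster_genes(feats)
        assert cs.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert cs.labels["a"] == cs.labels["b"]

    def test_anticorrelated_blocks_separate(self, rng):
        base = rng.normal(size=30)
        block1 = [base + rng.normal(0, 0.1, 30) for _ in range(4)]
        block2 = [-base + rng.normal(0, 0.1, 30) for _ in range(4)]
        feats = pd.DataFrame(block1 + block2,
                             index=[f"p{i}" for i in range(4)]
                             + [f"q{i}" for i in range(4)])
        cs = cluster_genes(feats)
        labs = cs.labels
        assert len(set(labs[[f"p{i}" for i in range(4)]])) == 1
        assert len(set(labs[[f"q{i}" for i in range(4)]])) == 1
        assert labs["p0"] != labs["q0"]

    def test_labels_named_by_descending_size(self, rng):
        base = rng.normal(size=30)
        feats = pd.DataFrame([base + rng.normal(0, 0.05, 30) for _ in range(5)]
                             + [-base + rng.normal(0, 0.05, 30) for _ in range(2)],
                             index=[f"g{i}" for i in range(7)])
        cs = cluster_genes(feats)
        assert (cs.labels == "C1").sum() == 5
        assert (cs.labels == "C2").sum() == 2

    def test_constant_vector_excluded_with_warning(self, rng, caplog):
        feats = pd.DataFrame([rng.normal(size=10), rng.normal(size=10),
                              np.full(10, 3.0)], index=["a", "b", "const"])
        with caplog.at_level("WARNING"):
            cs = cluster_genes(feats)
        assert "const" not in cs.labels.index

    def test_cluster_signatures_wrap_labels(self, rng):
        base = rng.normal(size=30)
        feats = pd.DataFrame([base, base + rng.normal(0, 0.01, 30),
                              -base, -base + rng.normal(0, 0.01, 30)],
                             index=list("abcd"))
        sigs = {s.name: s for s in cluster_signatures(cluster_genes(feats))}
        assert set(sigs) == {"C1", "C2"}
        assert sigs["C1"].members | sigs["C2"].members == set("abcd")


class TestSynexpression:
    def _corr_and_clusters(self, feats):
        ranks = feats.rank(axis=1)
        corr = pd.DataFrame(np.corrcoef(ranks.to_numpy()),
                            index=feats.index, columns=feats.index)
        return corr, cluster_genes(feats)

    def test_globally_correlated_genes_form_one_cluster(self, rng):
        base = rng.normal(size=40)
        feats = pd.DataFrame([base + rng.normal(0, 0.3, 40) for _ in range(6)],
                             index=[f"g{i}" for i in range(6)])
        corr, cs = self._corr_and_clusters(feats)
        groups = synexpression_groups(corr, cs, 0.15)
        assert len(groups) == 1 and len(groups[0]) == 6

    def test_uncorrelated_genes_form_no_cluster(self, rng):
        feats = pd.DataFrame(rng.normal(size=(6, 200)),
                             index=[f"g{i}" for i in range(6)])
        corr, cs = self._corr_and_clusters(feats)
        assert synexpression_groups(corr, cs, 0.15) == []

    def test_three_planted_blocks_recovered(self, rng):
        blocks = []
        for b in range(3):
            base = rng.normal(size=60)
            for i in range(4):
                noise = rng.normal(0, 1.0, 60)
                blocks.append(base + noise)   # within-block rho ~ 0.5
        feats = pd.DataFrame(blocks, index=[f"b{i//4}_g{i%4}" for i in range(12)])
        # threshold between the within-block mean (~0.5) and the mean of a
        # two-block union (12 pairs at 0.5 of 28, ~0.21), so exactly the
        # three planted blocks qualify
        corr, cs = self._corr_and_clusters(feats)
        groups = synexpression_groups(corr, cs, 0.3)
        assert len(groups) == 3
        assert sorted(tuple(sorted(g)) for g in groups) == sorted(
            tuple(sorted(f"b{b}_g{i}" for i in range(4))) for b in range(3))


@pytest.fixture(scope="module")
def mutex_run():
    cfg = GeneratorConfig(seed=1)
    cohort, truth = generate_pan_tumor(cfg)
    scores = metagene_score(cohort, truth.signature)
    tert = partition_tertiles(scores, cohort.group_of)
    low = restrict_to_low_tertile(cohort, tert)
    prog = sorted(set(truth.genes_with_role("programA"))
                  | set(truth.genes_with_role("programB")))
    binary = binarize_within_group(low.subset_genes(prog))
    return pairwise_fisher(binary), truth, prog


class TestPlantedProgramRecovery:
    def test_program_genes_recovered_by_thresholding(self, mutex_run):
        mm, truth, prog = mutex_run
        selected = threshold_mutex_genes(mm, -0.5, 1e-3)
        assert len(selected) >= 0.9 * len(prog)

    def test_low_tertile_restriction_preserves_groups(self, mutex_run):
        cfg = GeneratorConfig(seed=1, n_groups=3, samples_per_group=30,
                              n_genes=60, n_culprits=5, n_culprit_groups=2,
                              program_size_a=3, program_size_b=3)
        cohort, truth = generate_pan_tumor(cfg)
        scores = metagene_score(cohort, truth.signature)
        tert = partition_tertiles(scores, cohort.group_of)
        low = restrict_to_low_tertile(cohort, tert)
        assert set(low.groups) == set(cohort.groups)
        assert low.values.shape[1] == 3 * 10
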