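import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tfcensus import lifestyle as ls
from tfcensus.io_model import GenomeRecord


def genome(gid, n_orfs=2000, label="free-living"):
    return GenomeRecord(gid, f"Org {gid}", n_orfs, label)


def counts_frame(data, genomes):
    return pd.DataFrame(data, columns=[g.genome_id for g in genomes])


def rank_h_oracle(groups):
    """Brute-force tie-corrected Kruskal-Wallis H from first principles."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        size = len(g)
        r_sum = ranks[start:start + size].sum()
        h += r_sum**2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    return h / correction


class TestTfProportions:
    def test_simple_ratio(self):
        g = genome("G1", n_orfs=2000)
        counts = counts_frame([[100]], [g])
        summary = ls.tf_proportions(counts, [g])["free-living"]
        assert summary.proportions[0] == pytest.approx(0.05)
        assert summary.n_genomes == 1

    def test_unknown_label_fatal(self):
        g = GenomeRecord("G1", "Org", 2000, "pathogen")
        bad = g.__class__("G2", "Org", 1000, "pathogen")
        counts = counts_frame([[1, 1]], [g, bad])
        # bypass constructor validation to simulate a corrupt record
        object.__setattr__(bad, "lifestyle", "symbiont")
        with pytest.raises(ValueError, match="G2"):
            ls.tf_proportions(counts, [g, bad])

    def test_identical_genomes_equal_medians(self):
        genomes = [
            genome(f"G{i}", n_orfs=1000, label=label)
            for i, label in enumerate(
                ["free-living", "pathogen", "extremophile", "intracellular"] * 2
            )
        ]
        counts = counts_frame([[50] * 8], genomes)
        summaries = ls.tf_proportions(counts, genomes)
        medians = {s.median for s in summaries.values()}
        assert medians == {0.05}

    def test_outlier_detection(self):
        genomes = [genome(f"G{i}", n_orfs=1000) for i in range(10)]
        vals = [50] * 9 + [900]
        counts = counts_frame([vals], genomes)
        summary = ls.tf_proportions(counts, genomes)["free-living"]
        assert summary.outliers == (0.9,)

    def test_planted_lifestyle_ordering(self, small_dataset):
        from tfcensus import abundance as ab
        from tfcensus.io_model import assemble_architectures, filter_hits

        ds = small_dataset
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        counts = ab.count_families(archs, ds.catalog, ds.genomes)
        summaries = ls.tf_proportions(counts, ds.genomes)
        if "free-living" in summaries and "intracellular" in summaries:
            assert summaries["free-living"].median > summaries["intracellular"].median


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = ls.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(rank_h_oracle([[1, 2, 3], [1, 2, 3]]))

    def test_all_identical_observations(self):
        assert ls.kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_hand_computed_three_groups(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = ls.kruskal_wallis(groups)
        # ranks 1..9; rank sums 6, 15, 24 -> H = 12/90*(36/3+225/3+576/3)-30 = 7.2
        assert h == pytest.approx(7.2, abs=1e-12)
        assert h == pytest.approx(rank_h_oracle(groups), abs=1e-12)
        assert p == pytest.approx(scipy.stats.chi2.sf(7.2, 2), abs=1e-15)

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        groups = [rng.integers(0, 6, size=n).tolist() for n in (8, 13, 5, 9)]
        h, _ = ls.kruskal_wallis(groups)
        assert h == pytest.approx(rank_h_oracle(groups), abs=1e-10)

    def test_two_groups_equals_squared_mann_whitney_z(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 12).tolist()
        b = rng.normal(0.5, 1, 17).tolist()  # continuous: no ties
        h, _ = ls.kruskal_wallis([a, b])
        u = scipy.stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.uniform(0, 1, n).tolist() for n in (6, 9, 7)]
        h1, _ = ls.kruskal_wallis(groups)
        transformed = [[np.exp(3 * v) for v in g] for g in groups]
        h2, _ = ls.kruskal_wallis(transformed)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ls.kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            ls.kruskal_wallis([[1, 2], []])


class TestFamilyLifestyleRates:
    def test_simple_rate(self):
        g = genome("G1", n_orfs=1000)
        counts = counts_frame([[10]], [g])
        counts.index = ["FamA"]
        rates = ls.family_lifestyle_rates(counts, [g])
        assert rates.loc["FamA", "free-living"] == pytest.approx(0.01)

    def test_scale_invariance(self):
        genomes = [genome("G1", 1000), genome("G2", 3000)]
        counts = counts_frame([[10, 30], [2, 6]], genomes)
        counts.index = ["A", "B"]
        doubled_genomes = [genome("G1", 2000), genome("G2", 6000)]
        doubled = counts * 2
        r1 = ls.family_lifestyle_rates(counts, genomes)
        r2 = ls.family_lifestyle_rates(doubled, doubled_genomes)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_lifestyle_dropped(self, caplog):
        g = genome("G1", 1000)
        counts = counts_frame([[5]], [g])
        rates = ls.family_lifestyle_rates(counts, [g])
        assert list(rates.columns) == ["free-living"]

    def test_ubiquitous_family_near_equal_rates(self, small_dataset):
        from tfcensus import abundance as ab
        from tfcensus.io_model import assemble_architectures, filter_hits

        ds = small_dataset
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        counts = ab.count_families(archs, ds.catalog, ds.genomes)
        rates = ls.family_lifestyle_rates(counts, ds.genomes)
        # most abundant family occurs at a nonzero rate in every lifestyle
        top = rates.sum(axis=1).idxmax()
        assert (rates.loc[top] > 0).all()


class TestClusterFamilies:
    def test_identical_rows_merge_first_at_zero(self):
        rates = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["A", "B", "C"]
        )
        result = ls.cluster_families(rates, normalize_rows=False)
        assert result.merge_heights[0] == pytest.approx(0.0)

    def test_three_leaf_hand_computed_linkage(self):
        rates = pd.DataFrame(
            [[0.0, 0.0], [1.0, 1.0], [10.0, 10.0]], index=["A", "B", "C"]
        )
        result = ls.cluster_families(rates, normalize_rows=False, n_groups=2)
        # first merge {A, B} at L1 = 2; then average linkage to C: (18+20)/2 = 19
        assert result.merge_heights == pytest.approx((2.0, 19.0))
        assert result.flat_groups["A"] == result.flat_groups["B"]
        assert result.flat_groups["A"] != result.flat_groups["C"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rates = pd.DataFrame(
            rng.uniform(0, 1, size=(8, 4)), index=[f"F{i}" for i in range(8)]
        )
        r1 = ls.cluster_families(rates)
        r2 = ls.cluster_families(rates.sample(frac=1, random_state=1))
        assert r1.merge_heights == pytest.approx(r2.merge_heights)
        assert r1.flat_groups == r2.flat_groups

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(6)
        rates = pd.DataFrame(
            rng.uniform(0, 1, size=(12, 4)), index=[f"F{i}" for i in range(12)]
        )
        heights = ls.cluster_families(rates).merge_heights
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_newick_parses_with_all_leaves(self):
        import dendropy

        rng = np.random.default_rng(7)
        rates = pd.DataFrame(
            rng.uniform(0, 1, size=(6, 3)), index=[f"Fam{i}" for i in range(6)]
        )
        result = ls.cluster_families(rates)
        tree = dendropy.Tree.get(data=result.newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {f"Fam{i}" for i in range(6)}

    def test_uncentered_metric_option(self):
        rates = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 0.5]],
            index=["A", "B", "C"],
        )
        result = ls.cluster_families(
            rates, metric="uncentered", normalize_rows=False, n_groups=2
        )
        # A and B are proportional -> uncentered distance 0 -> first merge
        assert result.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        assert result.flat_groups["A"] == result.flat_groups["B"]

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            ls.cluster_families(pd.DataFrame([[1.0, 2.0]], index=["A"]))
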