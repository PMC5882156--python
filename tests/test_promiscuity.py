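import math

import numpy as np
import pytest
import sympy

from tfcensus import promiscuity as pr
from tfcensus import synthetic as syn
from tfcensus.io_model import (
    GenomeRecord,
    assemble_architectures,
    filter_hits,
)

from .conftest import make_hit


def dbd(protein_id, start=100, end=160, genome_id="G1", family="LysR"):
    return make_hit(protein_id=protein_id, genome_id=genome_id,
                    model_id=f"DBD_{family.replace('/', '_')}",
                    family_id=family, family_e_value=1e-9,
                    start=start, end=end)


def cd(protein_id, model_id, start, end, genome_id="G1"):
    return make_hit(protein_id=protein_id, genome_id=genome_id,
                    model_id=model_id, start=start, end=end)


class TestIafIvWs:
    def test_iaf_power_of_two(self):
        assert pr.iaf(1024, 1) == pytest.approx(10.0, abs=1e-15)

    def test_iaf_identity(self):
        assert pr.iaf(500, 500) == 0.0

    def test_iaf_high_precision_oracle(self):
        # log2(3000/12) = log2(250) via arbitrary-precision evaluation
        oracle = float(sympy.log(sympy.Rational(3000, 12), 2).evalf(30))
        assert pr.iaf(3000, 12) == pytest.approx(oracle, abs=1e-12)
        assert round(pr.iaf(3000, 12), 4) == 7.9658

    def test_iaf_absent_family_undefined(self):
        with pytest.raises(ValueError):
            pr.iaf(100, 0)
        with pytest.raises(ValueError):
            pr.iaf(10, 20)

    @pytest.mark.parametrize("f_d,expected", [(1, 1.0), (4, 0.25), (0, 1.0)])
    def test_iv(self, f_d, expected):
        assert pr.iv(f_d) == expected

    def test_iv_negative_raises(self):
        with pytest.raises(ValueError):
            pr.iv(-1)

    def test_ws_product(self):
        assert pr.ws(10.0, 0.2) == pytest.approx(2.0)
        assert pr.ws(7.3, 1.0) == 7.3

    def test_ws_monotone_in_f_d(self):
        iaf_v = pr.iaf(3000, 12)
        scores = [pr.ws(iaf_v, pr.iv(f)) for f in range(1, 11)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_partnerless_family_ranks_top(self):
        # f_d = 0 must give the maximal WS for a given abundance
        iaf_v = pr.iaf(2000, 5)
        assert pr.ws(iaf_v, pr.iv(0)) >= max(
            pr.ws(iaf_v, pr.iv(f)) for f in range(1, 20)
        )


class TestExtractCds:
    def test_dbd_only_no_partners(self, catalog3):
        archs = assemble_architectures([dbd("P1")], catalog3)
        ext = pr.extract_cds(archs, "LysR")
        assert ext.f_d("G1") == 0
        assert ext.global_cds == frozenset()

    def test_flanking_partners(self, catalog3):
        hits = [cd("P1", "CD_A", 1, 80), dbd("P1", 100, 160),
                cd("P1", "CD_B", 180, 300)]
        archs = assemble_architectures(hits, catalog3)
        ext = pr.extract_cds(archs, "LysR")
        assert ext.partners_by_genome["G1"] == frozenset({"CD_A", "CD_B"})

    def test_f_d_is_genome_level_union(self, catalog3):
        hits = [cd("P1", "CD_A", 1, 80), dbd("P1", 100, 160),
                dbd("P2", 1, 60), cd("P2", "CD_A", 80, 200)]
        archs = assemble_architectures(hits, catalog3)
        assert pr.extract_cds(archs, "LysR").f_d("G1") == 1

    def test_adjacent_vs_all_mode(self, catalog3):
        # CD_far is two segments away from the DBD
        hits = [dbd("P1", 1, 60), cd("P1", "CD_near", 80, 200),
                cd("P1", "CD_far", 220, 340)]
        archs = assemble_architectures(hits, catalog3)
        adj = pr.extract_cds(archs, "LysR", mode=pr.ADJACENCY_ADJACENT)
        allm = pr.extract_cds(archs, "LysR", mode=pr.ADJACENCY_ALL)
        assert adj.partners_by_genome["G1"] == frozenset({"CD_near"})
        assert allm.partners_by_genome["G1"] == frozenset({"CD_near", "CD_far"})
        # global CD set counts every non-DBD segment in both modes
        assert adj.global_cds == allm.global_cds == frozenset({"CD_near", "CD_far"})

    def test_global_cds_superset_of_partner_sets(self, small_dataset):
        ds = small_dataset
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        for fam in ds.catalog.families:
            ext = pr.extract_cds(archs, fam)
            for partners in ext.partners_by_genome.values():
                assert partners <= ext.global_cds


class TestComputeScores:
    @pytest.fixture
    def scored(self, catalog3):
        genomes = [GenomeRecord("G1", "Org1", 2048, "free-living")]
        hits = [dbd("P1", 1, 60), cd("P1", "CD_A", 80, 200),
                dbd("P2", 1, 60), cd("P2", "CD_B", 80, 200)]
        archs = assemble_architectures(hits, catalog3)
        return pr.compute_scores(archs, genomes, catalog3)

    def test_score_row_values(self, scored):
        row = scored[scored.family == "LysR"].iloc[0]
        assert row.P_t == 2048 and row.P_d == 2 and row.f_d == 2
        assert row.IAF == pytest.approx(10.0)
        assert row.WS == pytest.approx(5.0)

    def test_absent_family_emits_no_row(self, scored):
        assert (scored.family == "TetR/AcrR").sum() == 0

    def test_ws_identity_invariant(self, small_dataset):
        ds = small_dataset
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        scores = pr.compute_scores(archs, ds.genomes, ds.catalog)
        recomputed_iaf = np.log2(scores.P_t / scores.P_d)
        np.testing.assert_allclose(scores.IAF, recomputed_iaf, atol=1e-12)
        np.testing.assert_allclose(scores.WS, scores.IAF * scores.IV, atol=1e-15)
        assert (scores.P_d <= scores.P_t).all()
        assert ((scores.IV > 0) & (scores.IV <= 1)).all()

    def test_ws_vector_with_absent_zeros(self, scored):
        genomes = [GenomeRecord("G1", "Org1", 2048, "free-living"),
                   GenomeRecord("G2", "Org2", 1000, "pathogen")]
        vec = pr.ws_vector(scored, "LysR", genomes, include_absent=True)
        assert vec.shape == (2,) and vec[1] == 0.0


class TestBinning:
    def test_published_dataset_size(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(500, 10000, size=761)
        scheme = pr.bin_genomes(sizes)
        assert scheme.k == 11

    @pytest.mark.parametrize("n,k", [(2, 2), (761, 11), (1000, 11), (16, 5)])
    def test_sturges_formula(self, n, k):
        assert pr.sturges_k(n) == k

    def test_width_is_range_over_k(self):
        sizes = [1000.0, 2000.0, 5000.0, 9360.0]
        scheme = pr.bin_genomes(sizes)
        assert scheme.c == pytest.approx((9360 - 1000) / scheme.k)

    def test_bins_partition_range(self):
        rng = np.random.default_rng(1)
        sizes = rng.integers(800, 9000, size=200)
        scheme = pr.bin_genomes(sizes)
        idx = [scheme.assign(s) for s in sizes]
        assert all(0 <= i < scheme.k for i in idx)
        # boundary values fall in exactly one bin
        assert scheme.assign(sizes.min()) == 0
        assert scheme.assign(sizes.max()) == scheme.k - 1

    def test_zero_range_error(self):
        with pytest.raises(ValueError):
            pr.bin_genomes([3000, 3000, 3000])


class TestClassifyPromiscuity:
    def test_constant_vector(self):
        cls = pr.classify_promiscuity([2.5, 2.5, 2.5, 2.5])
        assert cls.cv == 0.0
        assert cls.label == pr.CLASS_HIGHLY_PROMISCUOUS

    @pytest.mark.parametrize(
        "cv,label",
        [(1.2, pr.CLASS_HIGHLY_PROMISCUOUS), (2.0, pr.CLASS_INTERMEDIATE),
         (4.0, pr.CLASS_MONOLITHIC)],
    )
    def test_published_range_mapping(self, cv, label):
        assert pr.classify_cv(cv) == label

    def test_strict_mode_gap_values_unclassified(self):
        assert pr.classify_cv(1.5, strict=True) == pr.CLASS_UNCLASSIFIED
        assert pr.classify_cv(3.0, strict=True) == pr.CLASS_UNCLASSIFIED
        assert pr.classify_cv(1.2, strict=True) == pr.CLASS_HIGHLY_PROMISCUOUS
        assert pr.classify_cv(4.0, strict=True) == pr.CLASS_MONOLITHIC

    def test_cv_against_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0.1, 5.0, size=50)
        cls = pr.classify_promiscuity(values)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert cls.cv == pytest.approx(math.sqrt(var) / mean, rel=1e-12)

    def test_zero_mean_undefined(self):
        cls = pr.classify_promiscuity([0.0, 0.0, 0.0])
        assert cls.label == pr.CLASS_UNDEFINED


class TestArchitectureCensus:
    def test_half_and_half(self, catalog3):
        hits = [dbd("P1"), dbd("P2", 1, 60), cd("P2", "CD_A", 80, 200)]
        archs = assemble_architectures(hits, catalog3)
        census = pr.architecture_census(archs)
        assert census == pytest.approx((0.5, 0.5, 0.0))

    def test_fractions_sum_to_one(self, small_dataset):
        ds = small_dataset
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        census = pr.architecture_census(archs)
        assert sum(census) == pytest.approx(1.0, abs=1e-9)

    def test_binomial_sampling_recovery(self):
        # ~10k TFs at p_monodomain = 0.32
        cfg = syn.SyntheticConfig(
            n_genomes=50, seed=13,
            families=(syn.FamilySpec(name="F1", base_rate=60.0,
                                     p_monodomain=0.32, size_slope=0.0),),
        )
        ds = syn.generate_dataset(cfg)
        hits = [h for hs in ds.hits_by_genome.values() for h in hs]
        archs = assemble_architectures(filter_hits(hits), ds.catalog)
        assert len(archs) >= 8000
        mono, _, _ = pr.architecture_census(archs)
        assert mono == pytest.approx(0.32, abs=0.02)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pr.architecture_census([])


class TestCdSharing:
    def test_equal_sets(self):
        s = pr.cd_sharing({"A": {"x", "y"}, "B": {"x", "y"}})
        assert s.loc["A", "B"] == 1.0 and s.loc["B", "A"] == 1.0

    def test_disjoint_sets(self):
        s = pr.cd_sharing({"A": {"x"}, "B": {"y"}})
        assert s.loc["A", "B"] == 0.0

    def test_asymmetric_overlap(self):
        s = pr.cd_sharing({"A": {"x", "y", "z"}, "B": {"x"}})
        assert s.loc["A", "B"] == pytest.approx(1 / 3)
        assert s.loc["B", "A"] == 1.0

    def test_empty_family_null_row(self):
        s = pr.cd_sharing({"A": {"x"}, "B": set()})
        assert np.isnan(s.loc["B", "A"])
        assert s.loc["A", "A"] == 1.0
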