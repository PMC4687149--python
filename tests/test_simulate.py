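"""Synthetic genotype, map, network and category generators."""

import numpy as np
import pytest

from sennet.dyadicity import count_dyads, dyadicity, expected_dyads, heterophilicity
from sennet.info_theory import all_pairs_ig, information_gain, mutual_information
from sennet.simulate import (
    PENETRANCE_MODELS,
    SyntheticGenotypeSpec,
    SyntheticNetworkSpec,
    generate_attributed_network,
    generate_categories,
    generate_genotypes,
    generate_snp_gene_map,
    penetrance_table,
    plant_epistatic_pair,
)


def hw_probs(q):
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def exact_mi_and_ig(table, q=0.5):
    """Analytic marginal MI and IG from a 3x3 penetrance table at HW MAF q.

    Independent oracle: builds the exact joint distribution over
    (g1, g2, case) and evaluates the plug-in formulas on probabilities.
    """
    pg = hw_probs(q)
    joint = pg[:, None, None] * pg[None, :, None] * np.stack([1 - table, table], axis=2)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_c = h(joint.sum(axis=(0, 1)))
    mi_a = h(joint.sum(axis=(1, 2))) + h_c - h(joint.sum(axis=1).ravel())
    mi_b = h(joint.sum(axis=(0, 2))) + h_c - h(joint.sum(axis=0).ravel())
    i_ab_c = h(joint.sum(axis=2).ravel()) + h_c - h(joint.ravel())
    return mi_a, mi_b, i_ab_c - mi_a - mi_b


class TestGenotypeSpec:
    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, planted_pairs=[(0, 10, "xor", 1.0)])
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, planted_pairs=[(2, 2, "xor", 1.0)])
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, missing_rate=0.6)
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, maf_range=(0.1, 0.7))
        with pytest.raises(ValueError):
            SyntheticGenotypeSpec(10, 50, 50, planted_pairs=[(0, 1, "nope", 1.0)])


class TestGenerateGenotypes:
    def test_study_shape(self):
        spec = SyntheticGenotypeSpec(n_snps=1422, n_cases=491, n_controls=791, seed=0)
        ds = generate_genotypes(spec)
        assert ds.genotypes.shape == (1422, 1282)
        assert int(ds.phenotype.sum()) == 491
        assert len(set(ds.snp_ids)) == 1422

    def test_alphabet_and_exact_class_counts(self):
        spec = SyntheticGenotypeSpec(20, 80, 120, missing_rate=0.05, seed=1)
        ds = generate_genotypes(spec)
        assert set(np.unique(ds.genotypes)) <= {-1, 0, 1, 2}
        assert int(ds.phenotype.sum()) == 80
        assert int((1 - ds.phenotype).sum()) == 120

    def test_zero_missing_rate_gives_complete_data(self):
        ds = generate_genotypes(SyntheticGenotypeSpec(15, 40, 40, missing_rate=0.0, seed=2))
        assert not ds.has_missing()

    def test_equal_seeds_are_bit_identical(self):
        spec = dict(n_snps=12, n_cases=30, n_controls=30, missing_rate=0.03)
        a = generate_genotypes(SyntheticGenotypeSpec(**spec, seed=9))
        b = generate_genotypes(SyntheticGenotypeSpec(**spec, seed=9))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)

    def test_planted_xor_pair_stands_out(self):
        spec = SyntheticGenotypeSpec(
            n_snps=20,
            n_cases=500,
            n_controls=500,
            maf_range=(0.5, 0.5),
            missing_rate=0.0,
            planted_pairs=[(2, 11, "xor", 1.0)],
            seed=3,
        )
        scores = all_pairs_ig(generate_genotypes(spec))
        vals = scores.pair_values()
        iu, ju = np.triu_indices(20, k=1)
        top = np.argmax(vals)
        assert (iu[top], ju[top]) == (2, 11)
        assert vals[top] > np.quantile(np.delete(vals, top), 0.99)


class TestPenetranceModels:
    def test_unknown_model_raises(self):
        with pytest.raises(ValueError):
            penetrance_table("additive", 0.5)

    def test_xor_effect_one_is_deterministic_and_purely_epistatic(self):
        table = penetrance_table("xor", 1.0)
        assert set(np.unique(table)) == {0.0, 1.0}
        mi_a, mi_b, ig = exact_mi_and_ig(table, q=0.5)
        assert mi_a == pytest.approx(0.0, abs=1e-12)
        assert mi_b == pytest.approx(0.0, abs=1e-12)
        assert ig == pytest.approx(1.0, abs=1e-12)

    def test_threshold_model_has_marginal_and_interaction_signal(self):
        mi_a, mi_b, ig = exact_mi_and_ig(penetrance_table("threshold", 0.5), q=0.5)
        assert mi_a > 1e-3 and mi_b > 1e-3
        assert ig > 1e-3

    def test_all_tables_are_valid_probabilities(self):
        for model in PENETRANCE_MODELS:
            t = penetrance_table(model, 0.7)
            assert np.all((0 <= t) & (t <= 1))


class TestPlantEpistaticPair:
    def test_xor_effect_one_gives_near_one_bit(self):
        ds = generate_genotypes(
            SyntheticGenotypeSpec(5, 2000, 2000, maf_range=(0.5, 0.5), missing_rate=0.0, seed=4)
        )
        planted = plant_epistatic_pair(ds, 1, 3, "xor", 1.0, seed=5)
        ig = information_gain(planted.genotypes[1], planted.genotypes[3], planted.phenotype)
        assert ig > 0.9

    def test_xor_marginal_mi_vanishes_at_large_n(self):
        ds = generate_genotypes(
            SyntheticGenotypeSpec(2, 5000, 5000, maf_range=(0.5, 0.5), missing_rate=0.0, seed=6)
        )
        planted = plant_epistatic_pair(ds, 0, 1, "xor", 1.0, seed=7)
        for i in (0, 1):
            assert mutual_information(planted.genotypes[i], planted.phenotype) < 0.01

    def test_zero_effect_is_indistinguishable_from_noise(self):
        # mean IG of a planted effect-0 pair across replicates stays within
        # Monte-Carlo error of unplanted pairs of the same size
        planted_igs, null_igs = [], []
        for rep in range(60):
            ds = generate_genotypes(
                SyntheticGenotypeSpec(4, 150, 150, missing_rate=0.0, seed=100 + rep)
            )
            p = plant_epistatic_pair(ds, 0, 1, "xor", 0.0, seed=200 + rep)
            planted_igs.append(information_gain(p.genotypes[0], p.genotypes[1], p.phenotype))
            null_igs.append(information_gain(p.genotypes[2], p.genotypes[3], p.phenotype))
        diff = np.mean(planted_igs) - np.mean(null_igs)
        se = np.sqrt(np.var(planted_igs) / 60 + np.var(null_igs) / 60)
        assert abs(diff) < 3 * se + 1e-9

    def test_invalid_indices_raise(self, random_dataset_factory):
        ds = random_dataset_factory(n_snps=4)
        with pytest.raises(ValueError):
            plant_epistatic_pair(ds, 2, 2, "xor", 1.0)


class TestSnpGeneMap:
    def test_study_scale_counts(self):
        mapping = generate_snp_gene_map(1422, 396, seed=0)
        assert len(mapping) == 1422
        assert len(set(mapping.values())) == 396

    def test_equal_counts_is_bijection(self):
        mapping = generate_snp_gene_map(5, 5, seed=1)
        assert len(set(mapping.values())) == 5

    def test_sizes_sum_to_snp_count(self):
        mapping = generate_snp_gene_map(6, 2, seed=2)
        assert len(mapping) == 6
        assert len(set(mapping.values())) == 2

    def test_more_genes_than_snps_raises(self):
        with pytest.raises(ValueError):
            generate_snp_gene_map(3, 4, seed=0)


class TestAttributedNetwork:
    def test_infeasible_edge_count_raises(self):
        with pytest.raises(ValueError):
            SyntheticNetworkSpec(n_vertices=5, n_edges=11, n1=2)

    def test_labels_have_exactly_n1_ones(self):
        net, labels = generate_attributed_network(SyntheticNetworkSpec(50, 80, 7, seed=0))
        assert sum(labels.values()) == 7
        assert net.n_vertices == 50
        assert net.n_edges == 80

    def test_random_regime_m11_matches_expectation(self):
        # Eq.-1 check: mean observed m11 over replicates ~ m11_expected
        m11s = []
        for s in range(300):
            net, labels = generate_attributed_network(
                SyntheticNetworkSpec(100, 200, 10, "random", seed=s)
            )
            m11s.append(count_dyads(net, labels).m11)
        expected, _ = expected_dyads(100, 200, 10)
        se = np.std(m11s) / np.sqrt(len(m11s))
        assert abs(np.mean(m11s) - expected) < 3 * se + 1e-9

    def test_dyadic_planting_pushes_d_above_one(self):
        hits = 0
        for s in range(100):
            net, labels = generate_attributed_network(
                SyntheticNetworkSpec(100, 200, 10, "dyadic", strength=5.0, seed=s)
            )
            if dyadicity(count_dyads(net, labels)) > 1:
                hits += 1
        assert hits >= 95

    def test_heterophilic_planting_pushes_h_above_one(self):
        hits = 0
        for s in range(100):
            net, labels = generate_attributed_network(
                SyntheticNetworkSpec(100, 200, 10, "heterophilic", strength=5.0, seed=s)
            )
            if heterophilicity(count_dyads(net, labels)) > 1:
                hits += 1
        assert hits >= 95

    def test_determinism(self):
        spec = SyntheticNetworkSpec(40, 60, 6, "dyadic", 3.0, seed=5)
        n1, l1 = generate_attributed_network(spec)
        n2, l2 = generate_attributed_network(spec)
        assert sorted(n1.graph.edges) == sorted(n2.graph.edges)
        assert l1 == l2


class TestCategories:
    def test_count_at_study_scale(self):
        genes = [f"gene{i:03d}" for i in range(185)]
        cats = generate_categories(genes, 808, size_range=(3, 50), seed=0)
        assert len(cats) == 808
        assert all(members <= set(genes) for members in cats.values())

    def test_fixed_size_range(self):
        cats = generate_categories(list("abcdefgh"), 5, size_range=(3, 3), seed=1)
        assert all(len(m) == 3 for m in cats.values())

    def test_disjoint_overflow_raises(self):
        with pytest.raises(ValueError):
            generate_categories(list("abcdef"), 4, size_range=(2, 2), overlap_allowed=False, seed=2)

    def test_empty_gene_list_raises(self):
        with pytest.raises(ValueError):
            generate_categories([], 3, size_range=(1, 1))
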