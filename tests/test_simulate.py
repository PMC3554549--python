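"""Simulation framework: spectra, etiologies, traits, study sampling."""

import numpy as np
import pytest

from bomp.simulate import (
    AA_LIKE,
    EtiologyConfig,
    EA_LIKE,
    ETIOLOGIES,
    CATEGORY_10_1_1_SAMPLER,
    Scenario,
    assign_causal_effects,
    build_gene_set_population,
    draw_case_control_study,
    sample_site_frequencies,
    simulate_genotypes,
    simulate_study,
    simulate_trait,
)


class TestSiteFrequencies:
    def test_ea_like_is_almost_entirely_rare(self):
        mafs = sample_site_frequencies(EA_LIKE, 10_000, np.random.default_rng(1))
        assert np.mean(mafs < 0.001) >= 0.90
        assert np.all((mafs > 0) & (mafs <= 0.5))

    def test_aa_like_occupies_all_three_bands(self):
        mafs = sample_site_frequencies(AA_LIKE, 10_000, np.random.default_rng(1))
        assert np.mean(mafs < 0.01) > 0.1
        assert np.mean((mafs >= 0.01) & (mafs <= 0.05)) > 0.1
        assert np.mean(mafs > 0.05) > 0.05

    def test_seed_determinism(self):
        a = sample_site_frequencies(AA_LIKE, 100, np.random.default_rng(9))
        b = sample_site_frequencies(AA_LIKE, 100, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_rejects_empty_request(self):
        with pytest.raises(ValueError):
            sample_site_frequencies(AA_LIKE, 0, np.random.default_rng(0))


class TestGenotypes:
    def test_binomial_heterozygote_fraction_at_half(self):
        g = simulate_genotypes(np.array([0.5]), 40_000, np.random.default_rng(2))
        het = np.mean(g == 1)
        se = np.sqrt(0.5 * 0.5 / 40_000)
        assert abs(het - 0.5) < 4 * se

    def test_rare_sites_mostly_reference(self):
        g = simulate_genotypes(np.full(50, 1e-4), 1_000, np.random.default_rng(3))
        assert np.mean(g == 0) > 0.99

    def test_values_in_allele_count_range(self):
        g = simulate_genotypes(np.array([0.3, 0.01]), 500, np.random.default_rng(4))
        assert set(np.unique(g)).issubset({0, 1, 2})

    def test_seed_determinism(self):
        a = simulate_genotypes(np.array([0.1, 0.2]), 50, np.random.default_rng(5))
        b = simulate_genotypes(np.array([0.1, 0.2]), 50, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_rejects_out_of_range_maf(self):
        with pytest.raises(ValueError):
            simulate_genotypes(np.array([0.6]), 10, np.random.default_rng(0))


class TestCausalEffects:
    def test_rare_etiology_ignores_common_variant(self):
        mafs = np.array([0.10, 0.005, 0.001])
        eff = assign_causal_effects(
            mafs, np.arange(3), EtiologyConfig(
                "rare", (0.0, 0.01), 0.5, null_fraction=0.0),
            np.random.default_rng(0),
        )
        assert eff[0] == 0.0 and eff[1] == 0.5 and eff[2] == 0.5

    def test_key_region_restricts_to_designated_segments(self):
        et = ETIOLOGIES["key_region"]
        mafs = np.full(4, 0.001)
        pos = np.array([5, 15, 105, 900])  # segments 0, 1, 10, 90
        eff = assign_causal_effects(
            mafs, pos, EtiologyConfig(
                "key_region", (0.0, 0.01), 1.0, null_fraction=0.0, key_region=True),
            np.random.default_rng(0), key_segments=[0, 10],
        )
        assert eff[0] == 1.0 and eff[2] == 1.0
        assert eff[1] == 0.0 and eff[3] == 0.0

    def test_null_fraction_one_silences_everything(self):
        et = EtiologyConfig("rare", (0.0, 0.01), 0.5, null_fraction=1.0)
        eff = assign_causal_effects(
            np.full(20, 0.002), np.arange(20), et, np.random.default_rng(0))
        assert not eff.any()

    def test_common_etiology_picks_single_variant(self):
        eff = assign_causal_effects(
            np.array([0.2, 0.3, 0.001]), np.arange(3), ETIOLOGIES["common"],
            np.random.default_rng(0))
        assert np.count_nonzero(eff) == 1 and eff.max() > 0
        assert eff[2] == 0.0

    def test_protective_effects_are_negative(self):
        et = ETIOLOGIES["rare_protect"]
        rng = np.random.default_rng(1)
        eff = assign_causal_effects(
            np.concatenate([np.full(30, 0.002), np.full(30, 0.03)]),
            np.arange(60), et, rng)
        assert (eff > 0).any() and (eff < 0).any()
        assert eff.min() == et.effect_protective

    def test_no_qualifying_variant_warns(self):
        with pytest.warns(UserWarning, match="no variant qualifies"):
            eff = assign_causal_effects(
                np.array([0.2]), np.array([0]), ETIOLOGIES["rare"],
                np.random.default_rng(0))
        assert not eff.any()


class TestTraits:
    def test_null_trait_is_standard_normal(self):
        g = np.zeros((100_000, 3))
        phi = simulate_trait(g, np.zeros(3), np.random.default_rng(6))
        assert abs(phi.mean()) < 4 / np.sqrt(100_000)
        assert abs(phi.var() - 1.0) < 0.02

    @pytest.mark.parametrize(
        "genotype,effects,mean",
        [
            ([1, 1, 1], [0.25, 0.25, 0.25], 0.75),
            ([2, 0, 1], [0.25, 0.25, 0.25], 0.75),
            ([1, 0, 0], [-0.5, 0.5, 0.5], -0.5),
        ],
    )
    def test_mean_shift_arithmetic(self, genotype, effects, mean):
        rng = np.random.default_rng(7)
        draws = np.array([
            simulate_trait(np.array(genotype), np.array(effects), rng)
            for _ in range(4000)
        ])
        assert abs(draws.mean() - mean) < 4 / np.sqrt(4000)


class TestStudySampling:
    def test_pool_sizes_follow_stated_fractions(self):
        sc = Scenario(population=10_000, n_case=100, n_ctrl=100, n_causal=0,
                      etiology="null")
        pop = build_gene_set_population(sc, np.random.default_rng(8))
        study = draw_case_control_study(pop, 100, 2_500,
                                        rng=np.random.default_rng(9))
        assert study.samples.n_cases == 100 and study.samples.n_controls == 2_500

    def test_oversized_request_names_the_pool(self):
        sc = Scenario(population=10_000, n_case=100, n_ctrl=100, n_causal=0,
                      etiology="null")
        pop = build_gene_set_population(sc, np.random.default_rng(8))
        with pytest.raises(ValueError, match="affected pool"):
            draw_case_control_study(pop, 200, 100, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="unaffected pool"):
            draw_case_control_study(pop, 50, 5_000, rng=np.random.default_rng(0))

    def test_case_and_control_sets_disjoint(self):
        sc = Scenario(population=5_000, n_case=30, n_ctrl=30)
        study = simulate_study(sc, np.random.default_rng(10))
        # cases come from the upper trait tail, controls from the lower
        case_traits = study.traits[study.samples.status]
        ctrl_traits = study.traits[~study.samples.status]
        assert case_traits.min() > ctrl_traits.max()

    def test_cases_enriched_for_causal_alleles(self):
        sc = Scenario(population=20_000, n_case=200, n_ctrl=200,
                      etiology="rare")
        study = simulate_study(sc, np.random.default_rng(11))
        causal = study.effects > 0
        dose = study.genotypes.values[:, causal].sum(axis=1)
        case_mean = dose[study.samples.status].mean()
        ctrl_mean = dose[~study.samples.status].mean()
        assert case_mean > ctrl_mean

    def test_gene_set_population_causal_gene_count(self):
        sc = Scenario(population=2_000, n_case=10, n_ctrl=10, n_genes=9,
                      n_causal=3, etiology="rare")
        pop = build_gene_set_population(sc, np.random.default_rng(12))
        n_affected_genes = sum(bool(g.effects.any()) for g in pop.layouts)
        assert n_affected_genes == 3
        assert sum(g.etiology != "null" for g in pop.layouts) == 3

    def test_all_null_genes_give_standard_normal_trait(self):
        sc = Scenario(population=50_000, n_case=10, n_ctrl=10, n_genes=3,
                      n_causal=0, etiology="null")
        pop = build_gene_set_population(sc, np.random.default_rng(13))
        assert abs(pop.traits.mean()) < 4 / np.sqrt(50_000)
        assert abs(pop.traits.var() - 1) < 0.05

    def test_population_determinism(self):
        sc = Scenario(population=1_000, n_case=10, n_ctrl=10, n_genes=2,
                      n_causal=1, etiology="rare")
        a = build_gene_set_population(sc, np.random.default_rng(14))
        b = build_gene_set_population(sc, np.random.default_rng(14))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.traits, b.traits)

    def test_etiology_sampler_category_frequencies(self):
        rng = np.random.default_rng(15)
        draws = [CATEGORY_10_1_1_SAMPLER.draw(rng) for _ in range(3_000)]
        frac_protect = np.mean(["protect" in d for d in draws])
        frac_common = np.mean([d == "common" for d in draws])
        assert abs(frac_protect - 1 / 12) < 0.02
        assert abs(frac_common - 1 / 12) < 0.02
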