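"""Generator ground truth: calibration, conservation and determinism."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from orthomarker.ortholog import p_distance
from orthomarker.synthetic import (
    SimConfig,
    expected_pairwise_mismatch,
    mutate,
    random_sequence,
    simulate_genome_panel,
    simulate_labeled_trees,
    simulate_site_calls,
    simulate_snp_matrix,
    simulate_trait_table,
    write_cohort,
    _decode,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_genomes": 0},
        {"within_clade_div": 1.2},
        {"theta_per_species": 0.6},
        {"n_monophyly_violations": -1},
        {"locus_len_range": (1, 10)},
        {"clade_labels": ("A",)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_violations_capped_by_species_count(self):
        with pytest.raises(ValueError):
            simulate_labeled_trees(
                SimConfig(n_species=4, n_monophyly_violations=4))


class TestSubstitutionModel:
    def test_zero_divergence_identity(self, rng):
        seq = random_sequence(rng, 500)
        assert np.array_equal(mutate(seq, 0.0, rng), seq)

    def test_pairwise_mismatch_matches_closed_form(self, rng):
        # two branches at q=0.025 each from a shared ancestor, 1000 bp:
        # closed form P(differ) = 2q(1-q) + (2/3)q^2
        q, L = 0.025, 1000
        p_expected = expected_pairwise_mismatch(q, q)
        root = random_sequence(rng, L)
        a, b = mutate(root, q, rng), mutate(root, q, rng)
        mismatches = int(np.sum(a != b))
        lo, hi = stats.binom.ppf([0.005, 0.995], L, p_expected)
        assert lo <= mismatches <= hi


class TestGenomePanel:
    def test_zero_within_clade_divergence_identical_copies(self):
        config = SimConfig(seed=1, n_loci_uce=5, n_loci_usco=2,
                           within_clade_div=0.0)
        panel = simulate_genome_panel(config)
        for locus in panel.loci:
            by_clade = {}
            for g, seq in locus.seqs.items():
                by_clade.setdefault(panel.clades[g], set()).add(seq)
            assert all(len(s) == 1 for s in by_clade.values())

    def test_zero_paralog_fraction_no_paralog_rows(self):
        config = SimConfig(seed=2, n_loci_uce=10, n_loci_usco=2,
                           paralog_frac=0.0)
        panel = simulate_genome_panel(config)
        assert not panel.truth["is_paralog"].any()

    def test_observed_divergence_within_binomial_envelope(self):
        config = SimConfig(seed=3, n_loci_uce=1, n_loci_usco=1,
                           locus_len_range=(1000, 1000),
                           within_clade_div=0.05)
        panel = simulate_genome_panel(config)
        locus = next(l for l in panel.loci if l.type == "UCE")
        same_clade = [g for g, c in panel.clades.items() if c == "Caelifera"]
        a = np.frombuffer(locus.seqs[same_clade[0]].encode(), dtype=np.uint8)
        b = np.frombuffer(locus.seqs[same_clade[1]].encode(), dtype=np.uint8)
        mismatches = int(np.sum(a != b))
        p_exp = expected_pairwise_mismatch(0.025, 0.025)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, p_exp)
        assert lo <= mismatches <= hi

    def test_truth_coordinates_recover_planted_sequences(self):
        config = SimConfig(seed=4, n_loci_uce=8, n_loci_usco=2,
                           paralog_frac=0.3)
        panel = simulate_genome_panel(config)
        by_id = {l.id: l for l in panel.loci}
        for row in panel.truth.itertuples():
            embedded = panel.genomes[row.genome][row.start:row.end]
            if not row.is_paralog:
                assert embedded == by_id[row.locus_id].seqs[row.genome]
            else:
                # paralogs are extra-divergent copies of the same locus
                ortho = by_id[row.locus_id].seqs[row.genome]
                assert p_distance(embedded, ortho) > 20.0

    def test_each_planted_locus_has_one_truth_record_per_genome(self):
        config = SimConfig(seed=5, n_loci_uce=6, n_loci_usco=3,
                           paralog_frac=0.0)
        panel = simulate_genome_panel(config)
        counts = panel.truth.groupby("locus_id").size()
        assert (counts == config.n_genomes).all()
        assert len(counts) == 9


class TestSiteCalls:
    def test_zero_theta_zero_het_records(self):
        config = SimConfig(seed=6, exon_bp=5_000, theta_per_species=0.0)
        cs = simulate_site_calls(config, "spX")
        het = cs.records["genotype"] == "0/1"
        assert het.sum() == 0

    def test_exon_mask_covers_configured_length(self):
        config = SimConfig(seed=7, exon_bp=3_141)
        cs = simulate_site_calls(config, "spX")
        assert sum(e - s for s, e in cs.exons) == 3_141
        assert len(cs.depth) == 3_141

    def test_quality_proportional_to_depth(self):
        config = SimConfig(seed=8, exon_bp=5_000, qual_per_read=30.0)
        cs = simulate_site_calls(config, "spX")
        assert np.allclose(cs.records["qual"],
                           30.0 * cs.records["depth"])

    def test_per_species_theta_mapping(self):
        config = SimConfig(seed=9, exon_bp=1_000,
                           theta_per_species={"a": 0.01, "*": 0.001})
        assert config.theta("a") == 0.01
        assert config.theta("other") == 0.001

    def test_depth_overdispersion_exceeds_poisson(self):
        config = SimConfig(seed=10, exon_bp=50_000, depth_mean=30.0,
                           depth_dispersion=5.0)
        cs = simulate_site_calls(config, "spX")
        # NB variance = m + m^2/k = 30 + 180 = 210 >> Poisson's 30
        assert cs.depth.var() > 100

    def test_monophyly_and_snp_and_calls_streams_independent(self):
        c = SimConfig(seed=11, exon_bp=1_000)
        cs1 = simulate_site_calls(c, "spX")
        simulate_snp_matrix(c)  # consuming another stage must not interfere
        cs2 = simulate_site_calls(c, "spX")
        assert cs1.records.equals(cs2.records)
        assert np.array_equal(cs1.depth, cs2.depth)


class TestTraitTable:
    def test_zero_effect_zero_noise_flat_response(self):
        config = SimConfig(seed=12, n_species=30, beta_riparian=0.0,
                           trait_noise_sd=0.0)
        table = simulate_trait_table(config)
        assert table["mean_pct_polymorphic"].nunique() == 1

    def test_noiseless_response_is_exact_linear_function(self):
        config = SimConfig(seed=13, n_species=30, trait_noise_sd=0.0)
        table = simulate_trait_table(config)
        log_prop = np.log(table["mean_pct_polymorphic"] / 100.0)
        expected = (config.log_diversity_intercept
                    + config.beta_riparian * table["riparian_indicator"])
        np.testing.assert_allclose(log_prop, expected, atol=1e-12)

    def test_supplied_diversities_define_baseline(self):
        config = SimConfig(seed=14, beta_riparian=0.0, trait_noise_sd=0.0)
        table = simulate_trait_table(
            config, species_diversities={"spA": 0.4, "spB": 0.8})
        got = dict(zip(table["species"], table["mean_pct_polymorphic"]))
        assert got["spA"] == pytest.approx(0.4)
        assert got["spB"] == pytest.approx(0.8)

    def test_ordinal_supports(self):
        table = simulate_trait_table(SimConfig(seed=15, n_species=200))
        assert set(table["iucn_category"]) <= {"LC", "NT", "VU", "EN", "CR"}
        assert table["riparian_indicator"].between(0, 3).all()
        assert table["elevation_level"].between(1, 5).all()


class TestDeterminism:
    def test_identical_config_byte_identical_cohort(self, tmp_path,
                                                    small_config):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_cohort(small_config, d1)
        write_cohort(small_config, d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*")
                        if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*")
                        if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        a = simulate_genome_panel(SimConfig(seed=1, n_loci_uce=3,
                                            n_loci_usco=1))
        b = simulate_genome_panel(SimConfig(seed=2, n_loci_uce=3,
                                            n_loci_usco=1))
        assert a.genomes != b.genomes
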