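"""Probe tiling, the candidate filter cascade and the panel manifest."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from orthomarker.errors import UndefinedValueError
from orthomarker.ortholog import p_distance
from orthomarker.panel import (
    UCE,
    USCO,
    CandidateLocus,
    PanelConfig,
    build_panel_manifest,
    consensus,
    design_probes,
    filter_candidates,
    tile_probes,
    usco_end_probes,
    variable_site_fraction,
    within_clade_divergence,
)


def make_locus(seqs, ltype=UCE, clades=None, locus_id="L1"):
    names = [f"g{i}" for i in range(len(seqs))]
    return CandidateLocus(
        locus_id, ltype, dict(zip(names, seqs)),
        clades=dict(zip(names, clades)) if clades else {},
    )


class TestTiling:
    @pytest.mark.parametrize(
        "length,probe_len,expected_offsets",
        [
            (340, 170, [0, 170]),       # exact tiling
            (169, 170, []),             # shorter than one probe -> none
            (511, 170, [0, 170, 340]),  # 1 bp remainder dropped
        ],
    )
    def test_offsets_and_remainder_drop(self, length, probe_len,
                                        expected_offsets):
        probes = tile_probes("A" * length, probe_len)
        assert [p.offset for p in probes] == expected_offsets
        assert all(p.length == probe_len for p in probes)

    def test_empty_sequence(self):
        assert tile_probes("", 170) == []

    @given(st.integers(min_value=0, max_value=2000),
           st.integers(min_value=1, max_value=300))
    @settings(max_examples=60, derandomize=True)
    def test_tiles_disjoint_and_conserve_length(self, length, probe_len):
        probes = tile_probes("A" * length, probe_len)
        assert len(probes) == length // probe_len
        spans = sorted((p.offset, p.offset + p.length) for p in probes)
        assert sum(e - s for s, e in spans) <= length
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # pairwise disjoint


class TestEndProbes:
    def test_two_ends_of_long_sequence(self):
        probes = usco_end_probes("A" * 400, 120, "u1")
        assert [(p.offset, p.offset + p.length) for p in probes] == [
            (0, 120), (280, 400)
        ]
        assert [p.role for p in probes] == ["end5", "end3"]

    def test_abutting_boundary_at_exactly_double_length(self):
        probes = usco_end_probes("A" * 240, 120)
        assert [(p.offset, p.offset + p.length) for p in probes] == [
            (0, 120), (120, 240)
        ]

    def test_short_sequence_single_probe_with_warning(self):
        with pytest.warns(UserWarning):
            probes = usco_end_probes("A" * 200, 120, "short")
        assert len(probes) == 1
        assert probes[0].length == 120

    def test_fiftyfour_sequences_give_108_probes(self):
        probes = [
            p for i in range(54)
            for p in usco_end_probes("ACGT" * 80, 120, f"usco-{i}")
        ]
        assert len(probes) == 108


class TestVariableSites:
    def test_identical_sequences(self):
        locus = make_locus(["ACGTACGTAC"] * 4)
        assert variable_site_fraction(locus) == 0.0

    def test_direct_count(self):
        # 10 columns, 6 variable between the two rows
        locus = make_locus(["AAAAAAAAAA", "CCCCCCAAAA"])
        assert variable_site_fraction(locus) == pytest.approx(0.6)

    def test_gap_columns_not_counted_as_variation(self):
        # column 1: A/- (single residue, not comparable); column 2: A/A
        locus = make_locus(["AA", "-A"])
        assert variable_site_fraction(locus) == 0.0

    def test_no_comparable_columns_undefined(self):
        with pytest.raises(UndefinedValueError):
            variable_site_fraction(make_locus(["A---", "-CCC"]))

    def test_random_uniform_pair_matches_three_quarters(self, rng):
        # P(two iid uniform bases differ) = 3/4; 3 s.e. band at 1000 columns
        bases = "ACGT"
        n = 1000
        a = "".join(rng.choice(list(bases), n))
        b = "".join(rng.choice(list(bases), n))
        frac = variable_site_fraction(make_locus([a, b]))
        se = (0.75 * 0.25 / n) ** 0.5
        assert abs(frac - 0.75) <= 3 * se


class TestWithinCladeDivergence:
    def test_identical_within_clade(self):
        locus = make_locus(["AAAA"] * 4, clades=["X", "X", "Y", "Y"])
        assert within_clade_divergence(locus) == {"X": 0.0, "Y": 0.0}

    def test_five_percent_pair(self):
        a = "A" * 100
        b = "C" * 5 + "A" * 95
        locus = make_locus([a, b], clades=["X", "X"])
        assert within_clade_divergence(locus)["X"] == pytest.approx(0.05)

    def test_three_members_equal_bruteforce_max(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(3)]
        locus = make_locus(seqs, clades=["X"] * 3)
        brute = max(
            p_distance(a, b) / 100.0
            for a, b in itertools.combinations(seqs, 2)
        )
        assert within_clade_divergence(locus)["X"] == pytest.approx(brute)

    def test_singleton_clades_omitted(self):
        locus = make_locus(["AAAA", "AAAA"], clades=["X", "Y"])
        assert within_clade_divergence(locus) == {}


class TestFilterCascade:
    def test_first_failing_rule_reported(self):
        few_genomes = make_locus(["A" * 200] * 5, locus_id="few")
        short = make_locus(["A" * 119] * 6, locus_id="short")
        kept, rejected = filter_candidates([few_genomes, short])
        assert kept == []
        assert dict(rejected) == {"few": "min_genomes",
                                  "short": "min_locus_len"}

    def test_hypervariable_and_divergent_rejected(self, rng):
        noisy = make_locus(
            ["".join(rng.choice(list("ACGT"), 200)) for _ in range(6)],
            clades=["X"] * 3 + ["Y"] * 3, locus_id="noisy",
        )
        base = "A" * 200
        div = make_locus(
            [base, "C" * 30 + "A" * 170] + [base] * 4,
            clades=["X"] * 3 + ["Y"] * 3, locus_id="div",
        )
        kept, rejected = filter_candidates([noisy, div])
        assert kept == []
        assert dict(rejected) == {"noisy": "max_variable_frac",
                                  "div": "max_within_clade_div"}

    def test_clean_locus_kept_and_usco_bypasses_variability(self, rng):
        clean = make_locus(["ACGT" * 50] * 6, clades=["X"] * 3 + ["Y"] * 3,
                           locus_id="clean")
        usco_noisy = make_locus(
            ["".join(rng.choice(list("ACGT"), 300)) for _ in range(5)],
            ltype=USCO, locus_id="usco",
        )
        kept, rejected = filter_candidates([clean, usco_noisy])
        assert {l.id for l in kept} == {"clean", "usco"}
        assert rejected == []

    def test_usco_shared_genome_rule(self):
        usco4 = make_locus(["A" * 300] * 4, ltype=USCO, locus_id="u4")
        kept, rejected = filter_candidates([usco4])
        assert kept == []
        assert rejected == [("u4", "min_genomes")]

    def test_tightening_thresholds_never_enlarges_kept_set(self, rng):
        from orthomarker.synthetic import SimConfig, simulate_genome_panel

        panel = simulate_genome_panel(
            SimConfig(seed=11, n_loci_uce=30, n_loci_usco=5))
        loose = PanelConfig()
        tight = PanelConfig(min_genomes=6, min_locus_len=150,
                            max_variable_frac=0.30,
                            max_within_clade_div=0.06)
        kept_loose, _ = filter_candidates(panel.loci, loose)
        kept_tight, _ = filter_candidates(panel.loci, tight)
        assert {l.id for l in kept_tight} <= {l.id for l in kept_loose}

    def test_agrees_with_bruteforce_recheck(self, small_config):
        """Oracle equivalence: an independent re-check of each rule on every
        synthetic locus agrees with the cascade verdict."""
        from orthomarker.panel import ungapped_length
        from orthomarker.synthetic import simulate_genome_panel

        panel = simulate_genome_panel(small_config)
        config = PanelConfig()
        kept, rejected = filter_candidates(panel.loci, config)
        verdicts = {l.id: True for l in kept}
        verdicts.update({lid: False for lid, _ in rejected})
        for locus in panel.loci:
            if locus.type == USCO:
                expected = locus.n_genomes >= config.usco_min_genomes
            else:
                expected = (
                    locus.n_genomes >= config.min_genomes
                    and ungapped_length(locus) >= config.min_locus_len
                    and variable_site_fraction(locus)
                    <= config.max_variable_frac
                    and all(d <= config.max_within_clade_div
                            for d in within_clade_divergence(locus).values())
                )
            assert verdicts[locus.id] == expected, locus.id


class TestManifest:
    def test_uce_plus_usco_end_probe_arithmetic(self):
        uces = [make_locus(["ACGT" * 50] * 6, locus_id=f"uce-{i}")
                for i in range(290)]
        uscos = [make_locus(["ACGT" * 100] * 6, ltype=USCO,
                            locus_id=f"usco-{i}") for i in range(54)]
        probes = design_probes(uces + uscos)
        manifest = build_panel_manifest(uces + uscos, probes)
        assert len(manifest) == 398
        counts = manifest.attrs["counts_by_type"]
        assert counts == {"UCE": 290, "USCO": 108}
        assert len(manifest) == sum(counts.values())

    def test_empty_panel(self):
        manifest = build_panel_manifest([], [])
        assert len(manifest) == 0

    def test_duplicate_locus_ids_rejected(self):
        dup = [make_locus(["A" * 200] * 6, locus_id="same"),
               make_locus(["C" * 200] * 6, locus_id="same")]
        with pytest.raises(ValueError, match="duplicate"):
            build_panel_manifest(dup, [])


def test_consensus_majority_rule():
    assert consensus(["ACGT", "ACGA", "ACTA"]) == "ACGA"
    assert consensus(["A-", "--"]) == "AN"
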