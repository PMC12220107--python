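import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tescope.landscape import family_coverage, kimura_divergence
from tescope.simulate import (
    CohortSpec,
    SimulationConfig,
    default_families,
    k2p_site_probabilities,
    mutate_copy,
    random_sequence,
    simulate_context_and_contacts,
    simulate_haplotype_pair,
    simulate_insertion_cohort,
    write_fixture,
)


class TestMutateCopy:
    def test_zero_divergence_identity(self, rng):
        cons = random_sequence(rng, 300)
        seq, truth = mutate_copy(cons, 0.0, rng=rng)
        assert seq == cons
        assert truth.n_transitions == 0 and truth.n_transversions == 0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy("A" * 100, -0.1)

    def test_saturating_k_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            mutate_copy("ACGT" * 50, 10.0)

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy("ACGT", 0.1)

    def test_truth_counts_match_realized_differences(self, rng):
        cons = random_sequence(rng, 2000)
        seq, truth = mutate_copy(cons, 0.15, rng=rng)
        assert len(seq) == len(cons)
        ts = tv = 0
        pur = set("AG")
        for a, b in zip(seq, cons):
            if a == b:
                continue
            if (a in pur) == (b in pur):
                ts += 1
            else:
                tv += 1
        assert (truth.n_transitions, truth.n_transversions) == (ts, tv)

    def test_estimator_consistency_against_truth(self, rng):
        # distance recovered from realized counts is unbiased around K
        for k in (0.05, 0.2):
            est = []
            for _ in range(40):
                _, truth = mutate_copy(random_sequence(rng, 4000), k, rng=rng)
                est.append(kimura_divergence(truth))
            assert abs(np.mean(est) - k) < 0.01

    def test_expected_ts_tv_ratio(self):
        p, q = k2p_site_probabilities(0.05, 2.0)
        assert p / q == pytest.approx(2.0, rel=0.05)

    def test_indels_change_length_but_not_truth_semantics(self, rng):
        cons = random_sequence(rng, 1000)
        seq, truth = mutate_copy(cons, 0.05, indel_rate=0.05, rng=rng)
        assert truth.n_sites < 1000           # deletions removed sites
        assert truth.n_transitions + truth.n_transversions <= truth.n_sites


class TestHaplotypePair:
    def test_truth_coverage_is_exact(self, sim_config):
        hap = simulate_haplotype_pair(sim_config)
        pa = family_coverage(hap.hits_a, hap.genome_length_a, "a")
        pb = family_coverage(hap.hits_b, hap.genome_length_b, "b")
        for _, row in hap.truth.iterrows():
            assert pa.per_family[row.family] == row.cov_a
            assert pb.per_family[row.family] == row.cov_b

    def test_size_difference_equals_planted_expansion(self, sim_config):
        hap = simulate_haplotype_pair(sim_config)
        assert (hap.genome_length_a - hap.genome_length_b
                == hap.truth.delta.sum())

    def test_no_expansion_gives_identical_truth(self):
        config = SimulationConfig(seed=2, expansion_bp={"CR1": 0})
        # zero-bp request still plants at least one copy; use a tiny one
        hap = simulate_haplotype_pair(config)
        unchanged = hap.truth[~hap.truth.expanded]
        assert (unchanged.delta == 0).all()

    def test_determinism(self):
        h1 = simulate_haplotype_pair(SimulationConfig(seed=9))
        h2 = simulate_haplotype_pair(SimulationConfig(seed=9))
        assert h1.hits_a == h2.hits_a
        assert h1.blocks_b == h2.blocks_b

    def test_oversized_planting_fatal(self):
        fams = tuple(
            f.__class__(**{**f.__dict__, "n_copies": 10000})
            for f in default_families()
        )
        with pytest.raises(ValueError, match="exceed"):
            simulate_haplotype_pair(
                SimulationConfig(seed=0, genome_length=10**6, families=fams)
            )

    def test_unknown_expansion_family_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, expansion_bp={"not-a-family": 1000})


class TestInsertionCohort:
    def test_genotype_structure_matches_categories(self, sim_config):
        cohort = simulate_insertion_cohort(sim_config)
        lineage_members = {}
        for s, lin in cohort.lineages.items():
            lineage_members.setdefault(lin, set()).add(s)
        for call in cohort.calls:
            t = cohort.truth.loc[call.call_id]
            carriers = {s for s, g in call.genotypes.items()
                        if g in ("0/1", "1/1")}
            missing = {s for s, g in call.genotypes.items() if g == "./."}
            if t.excluded_reason == "incomplete-genotype":
                assert missing
                continue
            if t.category == "shared":
                assert carriers == set(cohort.roster)
            else:
                lin = t.category.split(":", 1)[1]
                assert carriers == lineage_members[lin]

    def test_truth_label_completeness(self, sim_config):
        cohort = simulate_insertion_cohort(sim_config)
        assert sorted(cohort.truth.index) == sorted(
            c.call_id for c in cohort.calls
        )

    def test_tsd_probability_one_plants_everywhere(self):
        spec = CohortSpec(tsd_probability=1.0, short_fraction=0.0,
                          missing_fraction=0.0, te_fraction=1.0,
                          private_counts={"i-cell": 10, "ecto": 5, "endo": 5},
                          shared_count=20)
        cohort = simulate_insertion_cohort(SimulationConfig(seed=3, cohort=spec))
        assert (cohort.truth.tsd != ".").all()
        from tescope.insertions import detect_tsd
        for call in cohort.calls:
            left, right = cohort.flanks[call.call_id]
            assert detect_tsd(left, right) == cohort.truth.loc[call.call_id, "tsd"]

    def test_sequence_free_mode(self):
        spec = CohortSpec(emit_sequences=False, tsd_probability=0.0)
        cohort = simulate_insertion_cohort(SimulationConfig(seed=4, cohort=spec))
        assert all(c.sequence is None for c in cohort.calls)
        assert all(c.length >= 200 for c in cohort.calls)

    def test_single_sample_roster_rejected(self):
        spec = CohortSpec(samples={"only": "L"}, private_counts={"L": 5},
                          shared_count=5)
        with pytest.raises(ValueError):
            simulate_insertion_cohort(SimulationConfig(seed=0, cohort=spec))


class TestContextAndContacts:
    def test_ocr_overlap_tracks_multiplier(self):
        # i-cell multiplier 0.5 vs baseline 1.0, in expectation
        spec = CohortSpec(samples={"i": "i-cell", "o": "other"},
                          private_counts={"i-cell": 800, "other": 800},
                          shared_count=0, missing_fraction=0.0,
                          short_fraction=0.0, te_fraction=0.0,
                          tsd_probability=0.0, emit_sequences=False,
                          ocr_multipliers={"i-cell": 0.5, "other": 1.0})
        cfg = SimulationConfig(seed=6, cohort=spec)
        ctx = simulate_context_and_contacts(cfg)
        cohort = simulate_insertion_cohort(cfg, ocrs=ctx.ocrs)
        t = cohort.truth
        base = ctx.ocrs[0]
        ocr_fraction = sum(len(o) for o in ctx.ocrs) / spec.genome_length
        r_i = t[t.category == "specific:i-cell"].in_ocr.mean()
        r_o = t[t.category == "specific:other"].in_ocr.mean()
        assert r_i == pytest.approx(0.5 * ocr_fraction, abs=0.02)
        assert r_o == pytest.approx(1.0 * ocr_fraction, abs=0.03)

    def test_species_panel_row_structure(self, sim_config):
        ctx = simulate_context_and_contacts(sim_config)
        assert len(ctx.species_profiles) == sim_config.species.n_species
        assert len(ctx.species_core) == sim_config.species.n_core

    def test_contacts_are_cis_upper_triangular(self, sim_config):
        ctx = simulate_context_and_contacts(sim_config)
        assert (ctx.contacts.bin_j >= ctx.contacts.bin_i).all()
        assert (ctx.contacts.intensity > 0).all()


class TestWriteFixture:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=13)
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        p1 = write_fixture(cfg, d1)
        p2 = write_fixture(cfg, d2)
        assert sorted(p1) == sorted(p2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        p1 = write_fixture(SimulationConfig(seed=1), tmp_path / "a")
        p2 = write_fixture(SimulationConfig(seed=2), tmp_path / "b")
        assert not filecmp.cmp(p1["vcf"], p2["vcf"], shallow=False)
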