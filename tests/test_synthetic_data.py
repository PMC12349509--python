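"""Simulator dynamics, determinism, truth consistency and recovery checks."""

import numpy as np
import pandas as pd
import pytest

from gburden import (SimConfig, classify_deleterious, compute_burdens,
                     generate_dataset, output_digest, recover_parameters)
from gburden.synthetic_data import (Schedule, SimulationError, SiteModel,
                                    draw_schedule, regenerate_single_seed,
                                    selfing_offspring, simulate_accession,
                                    storage_mutation_step)
from gburden.variant_io import HET, HOM_ALT, HOM_REF

from conftest import small_sim_config


def neutral_site_model(n_sites):
    frame = pd.DataFrame({
        "chrom": ["Gm01"] * n_sites, "pos": np.arange(1, n_sites + 1),
        "ref": ["A"] * n_sites, "alt": ["G"] * n_sites,
        "role": ["deleterious"] * n_sites,
        "fitness_class": ["active"] * n_sites})
    return SiteModel(frame=frame, p_bg=np.zeros(n_sites),
                     s_site=np.zeros(n_sites),
                     mut_mask=np.ones(n_sites, dtype=bool))


class TestDynamics:
    def test_no_mutation_no_background_stays_reference(self):
        cfg = small_sim_config(mu_storage=0.0, mu_regen=0.0,
                               background_het=0.0, legacy_frac=0.0,
                               neutral_freq_mean=1e-9, seed=3)
        sim = generate_dataset(cfg)
        # nothing segregates, so a SNP caller reports no sites at all
        assert sim.variant_set.n_sites == 0

    def test_storage_mutation_is_irreversible_and_directional(self):
        rng = np.random.default_rng(0)
        sm = neutral_site_model(2000)
        geno = np.zeros(2000, dtype=np.int8)
        for _ in range(30):
            new = storage_mutation_step(geno, 0.01, sm.mut_mask, rng)
            assert (new >= geno).all()   # only ref -> het -> hom transitions
            geno = new
        assert (geno > 0).any()

    def test_lethal_homozygote_cannot_pass_regeneration(self):
        """With s=1, h=0 no offspring carrying a fresh homozygote survives."""
        rng = np.random.default_rng(1)
        sm = neutral_site_model(50)
        sm.s_site[:] = 1.0
        parent = np.zeros(50, dtype=np.int8)
        parent[:20] = HET
        for _ in range(200):
            child = regenerate_single_seed(parent, sm, h=0.0, mu_regen=0.0,
                                           rng=rng)
            assert not (child == HOM_ALT).any()

    def test_locked_lethal_homozygote_is_an_error(self):
        rng = np.random.default_rng(1)
        sm = neutral_site_model(10)
        sm.s_site[:] = 1.0
        parent = np.full(10, HOM_ALT, dtype=np.int8)
        with pytest.raises(SimulationError, match="lethal"):
            regenerate_single_seed(parent, sm, h=0.0, mu_regen=0.0, rng=rng)

    def test_neutral_selfing_halves_heterozygosity(self):
        """s=0, no mutation: E(het after one regeneration) = het/2."""
        rng = np.random.default_rng(42)
        k = 20
        sm = neutral_site_model(k)
        parent = np.full(k, HET, dtype=np.int8)
        reps = 10_000
        total = 0
        for _ in range(reps):
            child = regenerate_single_seed(parent, sm, h=0.0, mu_regen=0.0,
                                           rng=rng)
            total += int((child == HET).sum())
        assert total / reps == pytest.approx(k / 2, abs=0.1)

    def test_neutral_segregation_matches_mendelian_ratios(self):
        """One het site resolves 1/4 : 1/2 : 1/4 under s=0 selfing."""
        rng = np.random.default_rng(9)
        sm = neutral_site_model(1)
        parent = np.array([HET], dtype=np.int8)
        counts = np.zeros(3)
        reps = 12_000
        for _ in range(reps):
            counts[regenerate_single_seed(parent, sm, 0.0, 0.0, rng)[0]] += 1
        chi2 = ((counts - reps * np.array([0.25, 0.5, 0.25])) ** 2
                / (reps * np.array([0.25, 0.5, 0.25]))).sum()
        assert chi2 < 13.8  # chi-square_2 at p ~ 0.001

    def test_fast_path_matches_reference_offspring_sampler(self):
        """Rejection path (s=0) and the per-site oracle agree in distribution."""
        rng = np.random.default_rng(5)
        n = 40
        sm = neutral_site_model(n)
        parent = rng.integers(0, 3, n).astype(np.int8)
        mu = 0.02
        reps = 4000
        fast = np.zeros((3, n))
        for _ in range(reps):
            child = regenerate_single_seed(parent, sm, 0.0, mu, rng)
            for g in range(3):
                fast[g] += child == g
        ref = np.zeros((3, n))
        kids = selfing_offspring(parent, mu, reps, rng, sm.mut_mask)
        for g in range(3):
            ref[g] = (kids == g).sum(axis=0)
        # per-state frequencies agree within binomial noise
        np.testing.assert_allclose(fast / reps, ref / reps, atol=0.035)


class TestSchedules:
    def test_schedules_satisfy_metadata_invariants(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(0)
        for _ in range(500):
            s = draw_schedule(cfg, rng)
            s.validate()
            assert 18 <= s.y_acq <= 50
            assert s.y_last <= s.y_acq
            assert 0 <= s.r <= 10
            if s.r == 0:
                assert s.y_last == s.y_acq
            else:
                assert 4 <= s.y_last <= 25

    def test_trajectory_covers_every_year(self):
        cfg = small_sim_config()
        rng = np.random.default_rng(2)
        from gburden.synthetic_data import build_site_model
        sm = build_site_model(cfg, rng)
        sched = Schedule(y_acq=20, y_last=5, r=2, regen_times=(12, 5))
        geno, traj = simulate_accession(cfg, sched, sm, rng)
        assert traj["years_before_assay"].tolist() == list(range(20, -1, -1))
        assert geno.shape == (sm.n_sites,)
        assert set(np.unique(geno)) <= {HOM_REF, HET, HOM_ALT}


class TestDataset:
    def test_same_seed_gives_identical_outputs(self):
        cfg = small_sim_config(seed=21)
        assert output_digest(generate_dataset(cfg)) \
            == output_digest(generate_dataset(cfg))

    def test_different_seeds_differ(self):
        assert output_digest(generate_dataset(small_sim_config(seed=1))) \
            != output_digest(generate_dataset(small_sim_config(seed=2)))

    def test_study_scale_shapes(self, default_sim):
        sim = default_sim
        assert len(sim.metadata) == 190
        assert sim.truth["L"].iloc[0] <= 588
        dset = classify_deleterious(sim.annotation)
        burden = compute_burdens(sim.variant_set, dset)
        assert burden.shape[0] == 190
        assert (burden["L"] == sim.truth["L"].iloc[0]).all()

    def test_truth_record_matches_pipeline_burdens(self, default_sim):
        sim = default_sim
        dset = classify_deleterious(sim.annotation)
        burden = compute_burdens(sim.variant_set, dset)
        assert (burden["n_het"] == sim.truth["n_het"]).all()
        assert (burden["n_hom"] == sim.truth["n_hom"]).all()

    def test_burden_means_sit_at_calibration_targets(self, default_sim):
        """Default parameters reproduce the reference assay's burden scale."""
        dset = classify_deleterious(default_sim.annotation)
        burden = compute_burdens(default_sim.variant_set, dset)
        assert burden["B_het"].mean() == pytest.approx(0.015, abs=0.005)
        assert burden["B_hom"].mean() == pytest.approx(0.036, abs=0.008)
        assert burden["B_tot"].mean() == pytest.approx(0.051, abs=0.010)

    def test_decoy_only_annotation_wires_the_error_path(self):
        cfg = small_sim_config(l_sites=0, seed=4)
        sim = generate_dataset(cfg)
        dset = classify_deleterious(sim.annotation)
        assert len(dset) == 0
        from gburden.burden_stats import BurdenError
        with pytest.raises(BurdenError, match="no deleterious loci"):
            compute_burdens(sim.variant_set, dset)

    def test_pooled_mode_runs_and_keeps_shapes(self):
        cfg = small_sim_config(mode="pooled", n_samples=6, n_regen=5, seed=8)
        sim = generate_dataset(cfg)
        assert len(sim.metadata) == 6
        assert sim.variant_set.genotypes.shape[1] == 6


class TestRecovery:
    def test_signature_recovered_on_default_data(self, default_sim):
        report = recover_parameters(default_sim)
        assert report.all_passed, report.to_frame()

    def test_mutation_free_null_shows_no_burden_trends(self):
        """Without mutation input, burden-by-cycles slopes are null."""
        hits = 0
        for k in range(10):
            cfg = SimConfig(mu_storage=0.0, mu_regen=0.0, seed=300 + k)
            rep = recover_parameters(generate_dataset(cfg))
            by_name = {c.name: c for c in rep.checks}
            # het burden trend must not be 'recovered' from pure noise
            hits += by_name["B_het_increases_with_cycles"].passed
        assert hits <= 2

    def test_purging_off_lets_homozygotes_accumulate(self):
        """s=0 vs strong purging: the homozygous trend reappears."""
        strong = recover_parameters(
            generate_dataset(SimConfig(seed=77))).to_frame().set_index("check")
        off = recover_parameters(
            generate_dataset(SimConfig(s=0.0, s_legacy=0.0, seed=77))
        ).to_frame().set_index("check")
        assert off.loc["B_hom_flat_with_cycles", "slope"] \
            > strong.loc["B_hom_flat_with_cycles", "slope"]
        assert not off.loc["B_hom_flat_with_cycles", "passed"]
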