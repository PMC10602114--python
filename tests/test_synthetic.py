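"""Synthetic time-course generator and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from togcn import ConfigError, ValidationError
from togcn.compare import align_networks, classify_tfs
from togcn.network import CoexpressionCutoff, assign_levels_bfs, build_gcn, pairwise_pcc, suggest_seed
from togcn.preprocess import condition_mean_profiles
from togcn.synthetic import (
    SimConfig,
    SyntheticTruth,
    evaluate_recovery,
    generate,
    solve_wave_spacing,
    write_dataset,
)

from conftest import small_sim_config


def _build(sim, condition, seed_gene="TF_L01_01"):
    """Build one condition's network with the planted first TF as seed."""
    profiles = condition_mean_profiles(
        sim.expr_a if condition == sim.config.condition_a else sim.expr_b,
        sim.samples, condition,
    ).values
    tf_profiles = profiles.loc[[g for g in profiles.index if g in sim.annotation.tf_set]]
    pcc = pairwise_pcc(tf_profiles)
    gcn = build_gcn(pcc, CoexpressionCutoff.fixed(sim.config.pcc_cutoff))
    if seed_gene is None:
        seed_gene = suggest_seed(tf_profiles.loc[list(pcc.index)])[0]
    return assign_levels_bfs(gcn, seed_gene)


class TestSpacingSolver:
    def test_solution_satisfies_cutoff_constraints(self):
        w, cutoff, L, T = 0.8, 0.92, 11, 5
        delta = solve_wave_spacing(w, cutoff, L, T)
        t = np.arange(T, dtype=float)
        c0 = (T - 1) / 2 - delta * (L - 1) / 2
        centers = c0 + np.arange(L) * delta
        profiles = np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * w * w))
        corr = np.corrcoef(profiles)
        consec = min(corr[i, i + 1] for i in range(L - 1))
        skip = corr[np.triu_indices(L, 2)].max()
        assert consec > cutoff > skip

    def test_infeasible_request_names_constraint(self):
        with pytest.raises(ConfigError, match="cannot separate"):
            solve_wave_spacing(0.8, 0.999, 11, 5)

    def test_noise_awareness_widens_spacing_floor(self):
        quiet = solve_wave_spacing(0.8, 0.92, 11, 5, noise_sd=0.0, replicates=3)
        noisy = solve_wave_spacing(0.8, 0.92, 11, 5, noise_sd=0.1, replicates=3)
        assert noisy <= quiet  # attenuation tightens the consecutive constraint


class TestGenerate:
    def test_same_seed_reproduces_byte_identical_files(self, tmp_path):
        cfg = small_sim_config()
        from pathlib import Path

        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(generate(cfg), d1)
        p2 = write_dataset(generate(cfg), d2)
        for name in p1:
            assert Path(p1[name]).read_bytes() == Path(p2[name]).read_bytes()

    def test_different_seed_changes_data(self):
        a = generate(small_sim_config(rng_seed=1, noise_sd=0.05))
        b = generate(small_sim_config(rng_seed=2, noise_sd=0.05))
        assert not np.allclose(a.expr_a.values, b.expr_a.values)

    def test_truth_is_consistent_with_config(self, small_sim):
        cfg, truth = small_sim.config, small_sim.truth
        n_tfs = 1 + (cfg.n_levels - 1) * cfg.tfs_per_level
        assert len(truth.tf_genes) == n_tfs
        assert len(truth.shifted) == cfg.n_shifted_tfs
        assert set(truth.level_of.values()) == set(range(1, cfg.n_levels + 1))
        for g in truth.shifted:
            assert abs(truth.level_of_b[g] - truth.level_of[g]) == cfg.shift_levels
            assert 2 <= truth.level_of_b[g] <= cfg.n_levels
        # every level keeps unshifted TFs
        for lv in range(2, cfg.n_levels + 1):
            residents = [g for g in truth.tf_genes
                         if truth.level_of[g] == lv and g not in truth.shifted]
            assert residents

    def test_expression_nonnegative_with_noise(self):
        sim = generate(small_sim_config(noise_sd=0.5))
        assert (sim.expr_a.values.to_numpy() >= 0).all()
        assert (sim.expr_b.values.to_numpy() >= 0).all()

    def test_infeasible_shift_capacity_rejected(self):
        with pytest.raises(ConfigError, match="capacity"):
            small_sim_config(n_shifted_tfs=50)

    def test_truth_round_trips_through_dict(self, small_sim):
        back = SyntheticTruth.from_dict(small_sim.truth.to_dict())
        assert back == small_sim.truth


class TestEndToEndRecovery:
    def test_zero_noise_three_levels_recovered_exactly(self):
        """Down-scaled zero-noise chain is recovered with Spearman 1.0."""
        cfg = SimConfig(
            n_levels=3, tfs_per_level=2, n_coexpressed_per_level=3,
            n_background_genes=100, n_shifted_tfs=0, shift_levels=1,
            noise_sd=0.0, library_size_sd=0.0, planted_terms=[],
            n_null_terms=0, rng_seed=3,
        )
        sim = generate(cfg)
        togcn = _build(sim, cfg.condition_a)
        report = evaluate_recovery(togcn, sim.truth)
        assert togcn.n_levels == 3
        assert report["spearman"] == 1.0
        assert report["exact_match_fraction"] == 1.0

    def test_null_design_yields_no_specific_tfs(self):
        cfg = small_sim_config(n_shifted_tfs=0)
        sim = generate(cfg)
        ta = _build(sim, cfg.condition_a)
        tb = _build(sim, cfg.condition_b)
        comp = classify_tfs(align_networks(ta, tb))
        assert (comp.table["tf_class"] == "common").all()

    def test_recovery_degrades_with_noise_on_average(self):
        def mean_spearman(noise):
            vals = []
            for seed in range(3):
                cfg = small_sim_config(noise_sd=noise, rng_seed=seed)
                sim = generate(cfg)
                rho = evaluate_recovery(_build(sim, cfg.condition_a), sim.truth)["spearman"]
                # a collapsed network (too few leveled genes to rank) is
                # maximal degradation, not a missing observation
                vals.append(0.0 if np.isnan(rho) else rho)
            return np.mean(vals)

        assert mean_spearman(0.0) >= mean_spearman(0.4) - 1e-12


class TestEvaluateRecovery:
    def test_identity_and_reversal(self, small_sim):
        truth = small_sim.truth
        ident = evaluate_recovery(dict(truth.level_of), truth)
        assert ident["spearman"] == 1.0 and ident["exact_match_fraction"] == 1.0
        top = max(truth.level_of.values()) + 1
        reversed_levels = {g: top - lv for g, lv in truth.level_of.items()}
        assert evaluate_recovery(reversed_levels, truth)["spearman"] == -1.0

    def test_matches_rank_statistic_oracle(self, small_sim, rng):
        truth = small_sim.truth
        genes = sorted(truth.level_of)
        noisy = {g: int(truth.level_of[g] + rng.integers(0, 3)) for g in genes}
        got = evaluate_recovery(noisy, truth)["spearman"]

        def rankdata(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            sv = np.asarray(v, dtype=float)[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        ra = rankdata([noisy[g] for g in genes])
        rb = rankdata([truth.level_of[g] for g in genes])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_disjoint_namespaces_rejected(self, small_sim):
        with pytest.raises(ValidationError, match="share no genes"):
            evaluate_recovery({"zzz": 1}, small_sim.truth)
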