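"""Ground-truth guarantees of the synthetic data generators."""

import numpy as np
import pandas as pd
import pytest

from polphen.io import TL_START, parse_mutant_id
from polphen.pairs import DEFAULT_PAIR_CATEGORIES, default_pair_catalog
from polphen.synth import (DEFAULT_WT_SEQ, MECHANISM_BASELINE,
                           MECHANISM_BH_TL, MECHANISM_TL_GTP, SyntheticSpec,
                           additive_sequence_effects, generate_distance_dataset,
                           generate_fitness_dataset, generate_sequence_library,
                           wt_distance_profile)


class TestSpecValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticSpec(class_proportions={"GOF": 0.5, "LOF": 0.2,
                                            "lethal": 0.2, "WT": 0.2})

    @pytest.mark.parametrize("kw", [
        {"sigma_rep": -0.1}, {"missingness": 1.0}, {"delta_tl_gtp": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticSpec(**kw)


class TestFitnessGenerator:
    def test_zero_noise_is_exactly_linear(self):
        spec = SyntheticSpec(n_mutants=30, sigma_rep=0.0, missingness=0.0, seed=2)
        fitness, truth = generate_fitness_dataset(spec)
        p = truth["phenotype_value"].to_numpy()
        slopes = np.repeat(spec.slopes, spec.n_replicates)
        offsets = np.repeat(spec.offsets, spec.n_replicates)
        expected = p[:, None] * slopes[None, :] + offsets[None, :]
        assert np.allclose(fitness.to_numpy(), expected)

    def test_missing_fraction_within_binomial_interval(self):
        m = 0.1
        spec = SyntheticSpec(n_mutants=135, missingness=m, seed=3)
        fitness, _ = generate_fitness_dataset(spec)
        n_cells = fitness.size
        observed = fitness.isna().sum().sum() / n_cells
        tol = 3 * np.sqrt(m * (1 - m) / n_cells)
        assert abs(observed - m) < tol

    def test_seed_determinism(self):
        spec = SyntheticSpec(n_mutants=25, seed=7)
        f1, t1 = generate_fitness_dataset(spec)
        f2, t2 = generate_fitness_dataset(spec)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_phenotypes_override_class_draw(self, mutant_library):
        spec = SyntheticSpec(n_mutants=len(mutant_library), sigma_rep=0.0,
                             missingness=0.0, seed=4)
        planted = np.linspace(-2.0, 1.0, len(mutant_library))
        fitness, truth = generate_fitness_dataset(spec, mutants=mutant_library,
                                                  phenotypes=planted)
        assert np.allclose(truth["phenotype_value"], planted)
        slopes = np.repeat(spec.slopes, spec.n_replicates)
        offsets = np.repeat(spec.offsets, spec.n_replicates)
        assert np.allclose(fitness.to_numpy(),
                           planted[:, None] * slopes[None, :] + offsets[None, :])

    def test_phenotypes_near_class_anchors(self):
        spec = SyntheticSpec(n_mutants=135, seed=5)
        _, truth = generate_fitness_dataset(spec)
        anchors = {"GOF": 1.0, "LOF": -1.0, "lethal": -2.0, "WT": 0.0}
        for cls, group in truth.groupby("phenotype_class"):
            assert np.all(np.abs(group["phenotype_value"] - anchors[cls]) < 1.0)


class TestSequenceLibrary:
    def test_hamming_distance_equals_substitution_count(self, mutant_library):
        seqs = generate_sequence_library(DEFAULT_WT_SEQ, mutant_library,
                                         protonated_positions=())
        for m, seq in zip(mutant_library, seqs):
            diff = sum(a != b for a, b in zip(seq, DEFAULT_WT_SEQ))
            assert diff == len(m.substitutions)

    def test_double_mutant_hamming_two(self):
        m = parse_mutant_id("H1085Q-Q1078S")
        (seq,) = generate_sequence_library(DEFAULT_WT_SEQ, [m],
                                          protonated_positions=())
        assert sum(a != b for a, b in zip(seq, DEFAULT_WT_SEQ)) == 2

    def test_wt_mismatch_raises(self):
        bad = parse_mutant_id("G1103A")  # 1103 is E in the WT sequence
        with pytest.raises(ValueError):
            generate_sequence_library(DEFAULT_WT_SEQ, [bad])

    def test_library_unique_and_within_loop(self, mutant_library):
        labels = [m.label for m in mutant_library]
        assert len(set(labels)) == len(labels)
        for m in mutant_library:
            assert all(TL_START <= p <= TL_START + 30 for p in m.positions)


class TestAdditiveSequenceEffects:
    def test_double_equals_sum_of_singles(self, rng):
        eff = additive_sequence_effects(rng)
        s1 = parse_mutant_id("E1103G")
        s2 = parse_mutant_id("Q1078S")
        d = parse_mutant_id("E1103G-Q1078S")
        assert eff.phenotype(d) == pytest.approx(eff.phenotype(s1) + eff.phenotype(s2))

    def test_wt_is_zero(self, rng):
        eff = additive_sequence_effects(rng)
        assert eff.phenotype(parse_mutant_id("WT")) == 0.0


class TestDistanceGenerator:
    def test_catalog_has_62_unique_named_pairs(self):
        catalog = default_pair_catalog()
        names = [n for n, _ in catalog]
        assert len(catalog) == 62
        assert len(set(names)) == 62
        counts = pd.Series([c for _, c in catalog]).value_counts()
        assert set(counts.index) == {"TL-TL", "TL-BH", "BH-BH", "TL-GTP", "GTP-other"}

    def test_wt_profile_in_close_contact_range(self):
        wt = wt_distance_profile()
        assert (wt >= 2.0).all() and (wt <= 12.0).all()

    def test_zero_noise_profiles_equal_planted_means(self):
        spec = SyntheticSpec(n_mutants=40, sigma_d=0.0, seed=9)
        profiles, mech, _ = generate_distance_dataset(spec)
        wt = wt_distance_profile()
        tl_gtp = [n for n, c in DEFAULT_PAIR_CATEGORIES.items() if c == "TL-GTP"]
        bh_tl = [n for n, c in DEFAULT_PAIR_CATEGORIES.items() if c == "TL-BH"]
        for label, m in mech.items():
            row = profiles.distances.loc[label]
            if m == MECHANISM_BASELINE:
                assert np.allclose(row, wt)
            elif m == MECHANISM_TL_GTP:
                assert np.allclose(row[tl_gtp], wt[tl_gtp] + spec.delta_tl_gtp)
                assert np.allclose(row[bh_tl], wt[bh_tl])
            elif m == MECHANISM_BH_TL:
                assert np.allclose(row[bh_tl], wt[bh_tl] + spec.delta_bh_tl)
                assert np.allclose(row[tl_gtp], wt[tl_gtp])

    def test_planted_shift_recovered_in_sample_mean(self):
        spec = SyntheticSpec(n_mutants=135, sigma_d=0.3, seed=10)
        profiles, mech, _ = generate_distance_dataset(spec)
        wt = wt_distance_profile()
        tl_gtp = [n for n, c in DEFAULT_PAIR_CATEGORIES.items() if c == "TL-GTP"]
        sub = profiles.distances.loc[mech == MECHANISM_TL_GTP, tl_gtp]
        n = sub.size
        shift = float((sub - wt[tl_gtp]).to_numpy().mean())
        assert abs(shift - spec.delta_tl_gtp) < 3 * spec.sigma_d / np.sqrt(n)

    def test_profiles_strictly_positive_and_deterministic(self):
        spec = SyntheticSpec(n_mutants=30, sigma_d=2.0, seed=12)
        p1, m1, t1 = generate_distance_dataset(spec)
        p2, _, _ = generate_distance_dataset(spec)
        assert (p1.distances.to_numpy() > 0).all()
        pd.testing.assert_frame_equal(p1.distances, p2.distances)
        # mechanism assignment follows phenotype class
        cls = t1["phenotype_class"]
        assert set(m1[cls == "lethal"]) <= {MECHANISM_TL_GTP}
        assert set(m1[cls.isin(["GOF", "WT"])]) <= {MECHANISM_BASELINE}
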