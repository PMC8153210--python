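"""Subspace experiments at toy scale: validity, thresholds, reproducibility."""

import dataclasses

import pytest

from stoned.fixtures import CELECOXIB_SCAFFOLD
from stoned.mutate import MutationSpec, Representation
from stoned.subspace import (character_alphabet, expand_generation,
                             generate_subspace, scaffold_filter,
                             validity_fraction)
from conftest import canonical


@pytest.fixture(scope="module")
def small_report(celecoxib):
    return generate_subspace(celecoxib, 300, MutationSpec(),
                             Representation.SELFIES, rng_seed=11)


class TestGenerateSubspace:
    def test_selfies_strings_are_all_valid(self, toys):
        report = generate_subspace(toys["ethanol"], 100, MutationSpec(),
                                   Representation.SELFIES, rng_seed=0)
        assert report.n_strings_generated == 500  # 100 orderings x depth 5
        assert report.n_valid == report.n_strings_generated
        assert report.validity_percent == 100.0

    def test_seed_molecule_excluded_from_uniques(self, small_report,
                                                 celecoxib):
        assert canonical(celecoxib) not in small_report.unique_molecules

    def test_threshold_counts_are_monotone(self, small_report):
        c75 = small_report.threshold_count(0.75)
        c60 = small_report.threshold_count(0.60)
        c40 = small_report.threshold_count(0.40)
        assert c75 <= c60 <= c40 <= small_report.n_unique

    def test_percentages_use_unique_denominator(self, small_report):
        pct = small_report.threshold_percent(0.40)
        expected = 100.0 * small_report.threshold_count(0.40) \
            / small_report.n_unique
        assert pct == pytest.approx(expected)

    def test_similarities_and_percentages_bounded(self, small_report):
        assert all(0.0 <= s <= 1.0
                   for s in small_report.unique_molecules.values())
        for t in small_report.thresholds:
            assert 0.0 <= small_report.threshold_percent(t) <= 100.0

    def test_seeded_runs_are_identical(self, toys):
        r1 = generate_subspace(toys["toluene"], 50, MutationSpec(),
                               rng_seed=3)
        r2 = generate_subspace(toys["toluene"], 50, MutationSpec(),
                               rng_seed=3)
        assert r1.unique_molecules == r2.unique_molecules

    def test_parse_failure_raises(self):
        with pytest.raises(ValueError):
            generate_subspace("NOT_A_SMILES", 5, MutationSpec())


class TestValidityFraction:
    def test_selfies_is_always_100(self, toys):
        assert validity_fraction(toys["toluene"], 50, MutationSpec(),
                                 Representation.SELFIES) == 100.0

    def test_character_representations_lose_validity(self, celecoxib):
        spec = MutationSpec()
        smi = validity_fraction(celecoxib, 150, spec,
                                Representation.SMILES, rng_seed=1)
        assert 0.0 < smi < 50.0

    def test_character_alphabet_derivation(self):
        assert character_alphabet(["CCO", "C1=C1"]) == \
            ("1", "=", "C", "O")


class TestScaffoldFilter:
    def test_aromatic_scaffold_rejects_saturated_ring(self, toys):
        report = generate_subspace(toys["toluene"], 30, MutationSpec(),
                                   rng_seed=5)
        patched = dataclasses.replace(
            report, unique_molecules={canonical(toys["cyclohexane"]): 0.2,
                                      canonical(toys["toluene"]): 0.9})
        kept = scaffold_filter(patched, "c1ccccc1")
        assert canonical(toys["cyclohexane"]) not in kept.unique_molecules
        assert canonical(toys["toluene"]) in kept.unique_molecules
        assert kept.scaffold_retention == pytest.approx(0.5)

    def test_seed_matches_its_own_scaffold(self, celecoxib, small_report):
        patched = dataclasses.replace(
            small_report, unique_molecules={canonical(celecoxib): 1.0})
        kept = scaffold_filter(patched, CELECOXIB_SCAFFOLD)
        assert canonical(celecoxib) in kept.unique_molecules

    def test_terminal_mutations_retain_scaffold_more_often(self, celecoxib):
        random_rep = generate_subspace(celecoxib, 150, MutationSpec(),
                                       rng_seed=2)
        terminal_rep = generate_subspace(
            celecoxib, 150, MutationSpec(position_window=(0.9, 1.0)),
            rng_seed=2)
        r_rand = scaffold_filter(random_rep,
                                 CELECOXIB_SCAFFOLD).scaffold_retention
        r_term = scaffold_filter(terminal_rep,
                                 CELECOXIB_SCAFFOLD).scaffold_retention
        assert r_term > r_rand

    def test_invalid_query_raises(self, small_report):
        with pytest.raises(ValueError):
            scaffold_filter(small_report, "not-a-smarts[[[")


class TestExpandGeneration:
    def test_second_generation_grows_the_unique_set(self, toys):
        gen1 = generate_subspace(toys["toluene"], 10, MutationSpec(),
                                 rng_seed=7)
        gen2 = expand_generation(gen1, MutationSpec(), 10, rng_seed=7)
        assert gen2.n_unique > gen1.n_unique
        assert gen2.n_strings_generated == \
            gen1.n_strings_generated + gen1.n_unique * 10 * 5

    def test_union_keeps_first_generation(self, toys):
        gen1 = generate_subspace(toys["toluene"], 10, MutationSpec(),
                                 rng_seed=8)
        gen2 = expand_generation(gen1, MutationSpec(), 5, rng_seed=8)
        assert set(gen1.unique_molecules) <= set(gen2.unique_molecules)
        # first-generation similarities are preserved, not recomputed
        for smi, sim in gen1.unique_molecules.items():
            assert gen2.unique_molecules[smi] == sim

    def test_subsampling_caps_the_parent_set(self, toys):
        gen1 = generate_subspace(toys["toluene"], 20, MutationSpec(),
                                 rng_seed=9)
        full = expand_generation(gen1, MutationSpec(), 2, rng_seed=9)
        sampled = expand_generation(gen1, MutationSpec(), 2, rng_seed=9,
                                    sample_fraction=0.2)
        assert sampled.n_strings_generated < full.n_strings_generated
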