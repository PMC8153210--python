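"""Interpolation paths: padding, combinatorics, monotone filter, medians."""

import itertools
import math

import numpy as np
import pytest

from stoned import selfies as sf
from stoned.mutate import Representation, TokenString, encode
from stoned.pathing import (annotate_properties, count_paths,
                            extract_chemical_path, has_bridgehead,
                            increasing_indices, median_search, pad_align,
                            sample_many_paths, sample_raw_path, total_paths)
from stoned.similarity import joint_similarity
from conftest import canonical


class TestPadAlign:
    def test_equal_lengths_unchanged(self):
        a = encode("CCO", Representation.SELFIES)
        b = encode("CCN", Representation.SELFIES)
        pa, pb = pad_align(a, b)
        assert pa.tokens == a.tokens and pb.tokens == b.tokens

    def test_shorter_padded_at_tail(self):
        a = encode("CCO", Representation.SELFIES)
        b = encode("CCCCO", Representation.SELFIES)
        pa, pb = pad_align(a, b)
        assert len(pa.tokens) == len(pb.tokens) == 5
        assert pa.tokens[3:] == (sf.PAD_TOKEN, sf.PAD_TOKEN)

    def test_padding_preserves_decoding(self):
        a = encode("CC(C)Cl", Representation.SELFIES)
        b = encode("CCCCCCCC", Representation.SELFIES)
        pa, _ = pad_align(a, b)
        assert sf.decode(list(pa.tokens)) == sf.decode(list(a.tokens))

    def test_non_selfies_rejected(self):
        a = TokenString(Representation.SMILES, tuple("CCO"))
        with pytest.raises(ValueError):
            pad_align(a, a)


class TestRawPath:
    def test_identical_inputs_give_single_element_path(self):
        a = encode("CCO", Representation.SELFIES)
        raw = sample_raw_path(a, a, seed=0)
        assert raw.steps == (canonical("CCO"),)
        assert raw.mutated_position_order == ()

    def test_path_length_is_t_and_ends_at_target(self, drugs):
        a = encode(drugs["tadalafil"], Representation.SELFIES)
        b = encode(drugs["sildenafil"], Representation.SELFIES)
        raw = sample_raw_path(a, b, seed=1)
        t = len(raw.mutated_position_order)
        assert len(raw.steps) == t > 0
        assert raw.steps[-1] == canonical(drugs["sildenafil"])

    def test_every_intermediate_is_a_valid_molecule(self):
        # the SMILES-level route between these two has an invalid hole
        a = encode("CCC1CCC1CCC", Representation.SELFIES)
        b = encode("CCCCCCCCC", Representation.SELFIES)
        from rdkit import Chem
        for seed in range(10):
            raw = sample_raw_path(a, b, seed=seed)
            for step in raw.steps:
                assert step == "" or Chem.MolFromSmiles(step) is not None

    def test_deterministic_under_seed(self, drugs):
        a = encode(drugs["tadalafil"], Representation.SELFIES)
        b = encode(drugs["sildenafil"], Representation.SELFIES)
        assert sample_raw_path(a, b, 3).steps == sample_raw_path(a, b, 3).steps


class TestPathCounting:
    @pytest.mark.parametrize("t,expected", [(0, 1), (1, 1), (3, 6), (5, 120)])
    def test_count_paths(self, t, expected):
        assert count_paths(t) == expected

    def test_total_paths_sums_factorials(self):
        assert total_paths([2, 3]) == 8
        assert total_paths([]) == 0

    @pytest.mark.parametrize("t", [1, 2, 3, 4])
    def test_exhaustive_enumeration_matches_factorial(self, t):
        # brute force: enumerate substitution orders between two strings
        # differing in exactly t positions; count distinct step sequences
        start = ["[C]"] * (t + 2)
        target = ["[C]"] + ["[O]"] * t + ["[C]"]
        differing = [i for i in range(t + 2) if start[i] != target[i]]
        sequences = set()
        for perm in itertools.permutations(differing):
            current = list(start)
            steps = []
            for pos in perm:
                current[pos] = target[pos]
                steps.append(tuple(current))
            sequences.add(tuple(steps))
        assert len(sequences) == count_paths(t) == math.factorial(t)


class TestChemicalPath:
    def test_monotone_filter_on_a_known_trace(self):
        assert increasing_indices([0.2, 0.5, 0.4, 0.6]) == [0, 1, 3]

    def test_already_monotone_trace_unchanged(self):
        assert increasing_indices([0.1, 0.2, 0.3, 0.4]) == [0, 1, 2, 3]

    def test_first_step_exempt_second_drop_removed(self):
        # first mutated step may drop; a later drop may not
        assert increasing_indices([0.5, 0.3, 0.2, 0.6]) == [0, 1, 3]

    def test_similarity_strictly_increases_after_first_step(self, drugs):
        a = encode(drugs["tadalafil"], Representation.SELFIES)
        b = encode(drugs["sildenafil"], Representation.SELFIES)
        for seed in range(5):
            path = extract_chemical_path(sample_raw_path(a, b, seed))
            trace = path.sims_to_target
            assert all(x < y for x, y in zip(trace[1:-1], trace[2:]))
            assert path.molecules[-1] == canonical(drugs["sildenafil"])

    def test_sample_many_paths_unions_unique_molecules(self, drugs):
        found = sample_many_paths(drugs["tadalafil"], drugs["sildenafil"],
                                  n_ordering_pairs=2, repeats=2, seed=0)
        assert len(found) > 10
        for record in found.values():
            assert 0.0 <= record["sim_start"] <= 1.0
            assert 0.0 <= record["sim_target"] <= 1.0


class TestBridgehead:
    @pytest.mark.parametrize("name,expected", [
        ("norbornane", True),      # textbook bridged bicyclic
        ("benzene", False),
        ("naphthalene", False),    # ortho-fused, no bridge
        ("cyclohexane", False),
    ])
    def test_known_ring_systems(self, toys, name, expected):
        assert has_bridgehead(toys[name]) is expected

    def test_parse_failure_raises(self):
        with pytest.raises(ValueError):
            has_bridgehead("NOT_A_SMILES")


class TestAnnotateProperties:
    def test_logp_ordering_and_qed_range(self, toys):
        a = encode(toys["ethane"], Representation.SELFIES)
        raw = sample_raw_path(a, encode(toys["ethanol"],
                                        Representation.SELFIES), seed=0)
        path = annotate_properties(extract_chemical_path(raw), ["logp", "qed"])
        logp = dict(zip(path.molecules, path.properties["logp"]))
        assert logp[canonical("CC")] > logp[canonical("CCO")]
        assert all(0.0 <= q <= 1.0 for q in path.properties["qed"])

    def test_endpoint_annotations_match_direct_calls(self, drugs):
        from rdkit import Chem
        from rdkit.Chem import Descriptors
        a = encode(drugs["tadalafil"], Representation.SELFIES)
        b = encode(drugs["sildenafil"], Representation.SELFIES)
        path = annotate_properties(
            extract_chemical_path(sample_raw_path(a, b, 0)), ["logp"])
        for smi, value in zip(path.molecules, path.properties["logp"]):
            direct = Descriptors.MolLogP(Chem.MolFromSmiles(smi))
            assert value == pytest.approx(direct)

    def test_unknown_provider_rejected(self, toys):
        a = encode(toys["ethanol"], Representation.SELFIES)
        path = extract_chemical_path(sample_raw_path(a, a, 0))
        with pytest.raises(KeyError):
            annotate_properties(path, ["docking_affinity"])


class TestMedianSearch:
    def test_duplicate_references_recover_the_molecule(self, toys):
        smi = toys["toluene"]
        result = median_search([smi, smi], n_paths=3, seed=0)
        assert result[0].smiles == canonical(smi)
        assert result[0].joint == pytest.approx(1.0)

    def test_rank_one_beats_the_references_themselves(self, drugs):
        refs = [drugs["tadalafil"], drugs["sildenafil"]]
        result = median_search(refs, n_paths=10, seed=1)
        best = result[0].joint
        for ref in refs:
            assert best >= joint_similarity(ref, refs)

    def test_rank_one_beats_random_selfies_baseline(self, drugs):
        from stoned.mutate import random_selfies
        from stoned import selfies as _sf
        refs = [drugs["tadalafil"], drugs["sildenafil"]]
        result = median_search(refs, n_paths=10, seed=2)
        length = max(len(encode(r, Representation.SELFIES)) for r in refs)
        baseline = max(
            joint_similarity(_sf.decode(list(random_selfies(length, i).tokens)),
                             refs)
            for i in range(20))
        assert result[0].joint >= baseline

    def test_single_reference_rejected(self, toys):
        with pytest.raises(ValueError):
            median_search([toys["ethanol"]], n_paths=1)

    def test_bridgehead_filter_drops_flagged_candidates(self, drugs):
        refs = [drugs["tadalafil"], drugs["sildenafil"]]
        unfiltered = median_search(refs, n_paths=5, seed=3)
        filtered = median_search(refs, n_paths=5, seed=3,
                                 filter_bridgeheads=True)
        assert all(c.passes_bridgehead_filter for c in filtered)
        assert len(filtered) <= len(unfiltered)
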