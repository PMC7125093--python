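"""Chromosome decoding, domination logic, candidate evaluation, splits."""

import numpy as np
import pytest

from eegselect import (
    PARAMETER_TABLE,
    Chromosome,
    EvaluationConfig,
    ObjectiveVector,
    ParameterTable,
    decode_chromosome,
    dominates,
    evaluate_candidate,
    pareto_filter,
    random_subject_splits,
)


def _chrom(mask_bits, nu_bits, gamma_bits):
    return Chromosome(genes=tuple(mask_bits) + tuple(nu_bits) + tuple(gamma_bits),
                      n_channels=len(mask_bits))


class TestDecoding:
    def test_nu_field_zero_maps_to_smallest_value(self):
        chrom = _chrom([0] * 56, (0, 0, 0, 0), (0, 0, 0, 0))
        _, nu, gamma = decode_chromosome(chrom)
        assert nu == 0.000001 and gamma == 0.000001

    def test_gamma_field_fourteen_maps_to_point_nine(self):
        chrom = _chrom([0] * 56, (0, 0, 0, 0), (1, 1, 1, 0))
        _, _, gamma = decode_chromosome(chrom)
        assert gamma == 0.9

    def test_all_sixteen_indices_decode_table_values(self):
        for idx in range(16):
            bits = tuple(int(b) for b in f"{idx:04b}")
            chrom = _chrom([0] * 56, bits, bits)
            _, nu, gamma = decode_chromosome(chrom)
            assert nu == PARAMETER_TABLE[idx]
            assert gamma == PARAMETER_TABLE[idx]

    def test_full_channel_mask_popcount(self):
        chrom = _chrom([1] * 56, (0, 0, 0, 0), (0, 0, 0, 0))
        mask, _, _ = decode_chromosome(chrom)
        assert mask == frozenset(range(56))

    def test_gene_count_enforced(self):
        with pytest.raises(ValueError):
            Chromosome(genes=(0,) * 63, n_channels=56)

    def test_table_shape_enforced(self):
        with pytest.raises(ValueError):
            ParameterTable(values=(0.1,) * 15)


class TestDomination:
    def test_dominates_basics(self):
        assert dominates((1, 0.2), (2, 0.2))
        assert not dominates((1, 0.3), (2, 0.2))
        assert not dominates((1, 0.2), (1, 0.2))

    def test_single_candidate_kept(self):
        o = ObjectiveVector(n_channels=3, accuracy=0.9, tar=0.8, trr=0.7)
        assert pareto_filter([o]) == [o]

    def test_weak_domination_on_ties(self):
        a = ObjectiveVector(n_channels=2, accuracy=0.7, tar=0.8, trr=0.8)
        b = ObjectiveVector(n_channels=3, accuracy=0.7, tar=0.8, trr=0.8)
        assert pareto_filter([a, b]) == [a]

    def test_duplicates_collapse(self):
        a = ObjectiveVector(n_channels=2, accuracy=0.7, tar=0.8, trr=0.8)
        assert len(pareto_filter([a, a, a])) == 1

    def test_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(0)
        candidates = [
            ObjectiveVector(n_channels=int(rng.integers(1, 10)),
                            accuracy=float(rng.random()),
                            tar=float(rng.random()), trr=float(rng.random()))
            for _ in range(20)
        ]
        images = [c.minimization() for c in candidates]
        expected = []
        seen = set()
        for i, img in enumerate(images):
            if img in seen:
                continue
            if not any(dominates(o, img) for j, o in enumerate(images) if j != i):
                expected.append(candidates[i])
                seen.add(img)
        assert pareto_filter(candidates) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pareto_filter([])


class TestCandidateEvaluation:
    def test_n_channels_equals_popcount(self, oracle_instance):
        genes = (1, 0, 1, 1, 0, 0, 0, 1) + oracle_instance.tail
        obj = oracle_instance.evaluator(genes)
        assert obj.n_channels == 4

    def test_empty_mask_penalized_with_sentinel(self, oracle_instance):
        genes = (0,) * 8 + oracle_instance.tail
        obj = oracle_instance.evaluator(genes)
        assert not obj.feasible
        assert obj.minimization() == (9.0, 1.0, 1.0, 1.0)

    def test_sentinel_shape_for_full_montage(self):
        assert ObjectiveVector.sentinel(56).minimization() == (57.0, 1.0, 1.0, 1.0)

    def test_deterministic(self, oracle_instance):
        genes = (1, 1, 1, 0, 0, 0, 0, 0) + oracle_instance.tail
        a = oracle_instance.evaluator(genes)
        b = oracle_instance.evaluator(genes)
        assert a == b

    def test_informative_mask_scores_high_on_easy(self, easy_bench):
        # channels carrying the subject signatures, nu=0.01, gamma=0.1
        genes = [0] * 24
        for i in (0, 1, 2, 3):
            genes[i] = 1
        genes[16:20] = [0, 1, 0, 1]
        genes[20:24] = [0, 1, 1, 0]
        obj = evaluate_candidate(
            Chromosome(genes=tuple(genes), n_channels=16),
            easy_bench.cache, easy_bench.split, EvaluationConfig(cv_folds=10))
        assert obj.accuracy >= 0.95
        assert obj.tar >= 0.9 and obj.trr >= 0.9


class TestSubjectSplits:
    def test_half_and_half_disjoint(self):
        subjects = [f"S{i:02d}" for i in range(1, 27)]
        splits = random_subject_splits(subjects, n_splits=10, seed=0)
        assert len(splits) == 10
        for split in splits:
            assert len(split.non_intruders) == 13
            assert len(split.intruders) == 13
            assert not split.non_intruders & split.intruders
            assert split.non_intruders | split.intruders == set(subjects)

    def test_odd_count_extra_goes_to_non_intruders(self):
        splits = random_subject_splits(["a", "b", "c", "d", "e"], n_splits=1, seed=1)
        assert len(splits[0].non_intruders) == 3
        assert len(splits[0].intruders) == 2

    def test_reproducible_under_seed(self):
        subjects = [f"S{i}" for i in range(8)]
        assert random_subject_splits(subjects, 5, seed=3) == \
            random_subject_splits(subjects, 5, seed=3)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            random_subject_splits(["only"], 1, seed=0)
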