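"""Dataset round trips, validation errors, feature cache and report writers."""

import numpy as np
import pandas as pd
import pytest

from eegselect import (
    EpochSet,
    FeatureCache,
    SubjectSplit,
    channel_overlap_summary,
    load_epochset,
    read_pareto_report,
    save_epochset,
    write_pareto_report,
)
from eegselect.errors import (
    ChannelCountError,
    DatasetError,
    EmptyFrontError,
    MissingManifestError,
)
from eegselect.optimize import Chromosome, FrontMember, ObjectiveVector, ParetoFront


class TestEpochSetRoundTrip:
    def test_bitwise_round_trip(self, tiny_epochset, tmp_path):
        save_epochset(tiny_epochset, tmp_path / "ds")
        loaded = load_epochset(tmp_path / "ds")
        assert loaded.equals(tiny_epochset)
        for key in tiny_epochset.epochs:
            assert np.array_equal(loaded.epochs[key], tiny_epochset.epochs[key])

    def test_missing_manifest(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(MissingManifestError):
            load_epochset(tmp_path / "empty")

    def test_channel_count_mismatch_names_file(self, tiny_epochset, tmp_path):
        save_epochset(tiny_epochset, tmp_path / "ds")
        # drop one channel row from one session file
        victim = next((tmp_path / "ds").glob("epochs_S01_1.tsv"))
        frame = pd.read_csv(victim, sep="\t")
        frame.iloc[:-1].to_csv(victim, sep="\t", index=False)
        with pytest.raises(ChannelCountError) as exc:
            load_epochset(tmp_path / "ds")
        assert "epochs_S01_1.tsv" in str(exc.value)


class TestEpochSetValidation:
    def test_channel_count_enforced(self):
        with pytest.raises(ChannelCountError):
            EpochSet(montage=("A", "B", "C"), sampling_rate=200.0,
                     epochs={("S1", "1"): np.zeros((2, 2, 50))})

    def test_positive_sampling_rate(self):
        with pytest.raises(DatasetError):
            EpochSet(montage=("A",), sampling_rate=0.0,
                     epochs={("S1", "1"): np.zeros((1, 1, 50))})

    def test_channel_indices_lookup(self, tiny_epochset):
        labels = list(tiny_epochset.montage[:2])
        assert tiny_epochset.channel_indices(labels) == [0, 1]
        with pytest.raises(DatasetError):
            tiny_epochset.channel_indices(["NOPE"])


class TestSubjectSplit:
    def test_disjointness_enforced(self):
        with pytest.raises(DatasetError):
            SubjectSplit(non_intruders=["S1", "S2"], intruders=["S2", "S3"])

    def test_both_sides_non_empty(self):
        with pytest.raises(DatasetError):
            SubjectSplit(non_intruders=[], intruders=["S1"])


class TestFeatureCache:
    def test_round_trip(self, tiny_cache, tmp_path):
        tiny_cache.save(tmp_path / "cache.tsv")
        loaded = FeatureCache.load(tmp_path / "cache.tsv")
        assert loaded.montage == tiny_cache.montage
        assert set(loaded.blocks) == set(tiny_cache.blocks)
        for key in tiny_cache.blocks:
            assert np.allclose(loaded.blocks[key], tiny_cache.blocks[key],
                               rtol=0, atol=0)

    def test_complete_over_any_mask(self, tiny_epochset, tiny_cache):
        assert tiny_cache.is_complete_for(tiny_epochset)
        full = tiny_cache.instance_matrix("S03", "2", range(6))
        sub = tiny_cache.instance_matrix("S03", "2", [1, 4])
        assert full.shape[1] == 6 * 8 and sub.shape[1] == 16
        assert np.array_equal(sub[:, :8], full[:, 8:16])


def _member(n_channels, acc, tar, trr, nu=0.01, gamma=0.1, n_total=6):
    genes = [0] * (n_total + 8)
    for i in range(n_channels):
        genes[i] = 1
    chrom = Chromosome(genes=tuple(genes), n_channels=n_total)
    obj = ObjectiveVector(n_channels=n_channels, accuracy=acc, tar=tar, trr=trr)
    return FrontMember(chromosome=chrom, objectives=obj, nu=nu, gamma=gamma,
                       channel_indices=frozenset(range(n_channels)))


class TestParetoReport:
    def test_rows_sorted_by_channel_count(self, tmp_path):
        front = ParetoFront(members=[_member(3, 0.9, 0.8, 0.7),
                                     _member(1, 0.5, 0.9, 0.9)])
        path = tmp_path / "report.tsv"
        write_pareto_report(front, path, montage=list("ABCDEF"))
        frame = read_pareto_report(path)
        assert list(frame["n_channels"]) == [1, 3]
        assert frame.iloc[1]["channels"] == "A B C"

    def test_parse_back_matches_front(self, tmp_path):
        front = ParetoFront(members=[_member(2, 0.875, 0.75, 0.625,
                                             nu=0.0001, gamma=0.9)])
        path = tmp_path / "report.tsv"
        write_pareto_report(front, path, montage=list("ABCDEF"))
        row = read_pareto_report(path).iloc[0]
        assert row["accuracy"] == 0.875 and row["TAR"] == 0.75
        assert row["nu"] == 0.0001 and row["gamma"] == 0.9

    def test_empty_front_rejected(self, tmp_path):
        with pytest.raises(EmptyFrontError):
            write_pareto_report(ParetoFront(members=[]), tmp_path / "r.tsv",
                                montage=list("ABCDEF"))


class TestChannelOverlap:
    def test_hand_example(self):
        frame = channel_overlap_summary([{"A", "B"}, {"B", "C"}])
        counts = dict(zip(frame["label"], frame["count"]))
        assert counts == {"A": 1, "B": 2, "C": 1}

    def test_identical_subsets(self):
        frame = channel_overlap_summary([{"X", "Y"}] * 3)
        assert set(frame["count"]) == {3}

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        labels = [f"C{i}" for i in range(10)]
        subsets = [set(rng.choice(labels, size=5, replace=False))
                   for _ in range(3)]
        frame = channel_overlap_summary(subsets)
        for _, row in frame.iterrows():
            assert row["count"] == sum(row["label"] in s for s in subsets)
        assert set(frame["label"]) == set().union(*subsets)

    def test_needs_two_subsets(self):
        with pytest.raises(ValueError):
            channel_overlap_summary([{"A"}])
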