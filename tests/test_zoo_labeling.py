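"""Menagerie labeling: percentile rule, statistics, candidate selection."""

import itertools

import numpy as np
import pytest

from zoochimera.errors import (
    ConstraintViolationError,
    EmptyInputError,
    InsufficientPopulationError,
    InsufficientSamplesError,
)
from zoochimera.matching_fusion import distance
from zoochimera.zoo_labeling import (
    ZooConfig,
    filter_valid_individuals,
    finalize_labels,
    identify_goats,
    identify_lambs,
    intra_class_dispersion,
    label_modality,
    mean_inter_class_distance,
    percentile_index,
    reconcile_shared_labels,
    round_half_up,
)

from conftest import make_dataset, random_dataset


@pytest.mark.parametrize(
    "p,n,expected",
    [(70, 56, 39.7), (30, 10, 3.5), (50, 1, 1.0), (70, 10, 7.5), (30, 56, 17.3)],
)
def test_percentile_index(p, n, expected):
    assert percentile_index(p, n) == pytest.approx(expected, abs=1e-12)


def test_percentile_index_empty_population():
    with pytest.raises(EmptyInputError):
        percentile_index(50, 0)


def test_round_half_up():
    assert [round_half_up(x) for x in (3.5, 5.6, 17.3, 2.0)] == [4, 6, 17, 2]


class TestFilterValid:
    def test_missing_session_excluded(self):
        ds = make_dataset(
            {
                "full": {"s1": [[0.0]], "s2": [[0.0]]},
                "partial": {"s1": [[1.0]]},
            },
            session_order=["s1", "s2"],
        )
        assert filter_valid_individuals(ds) == ["full"]

    def test_all_present_is_identity(self, two_by_two):
        assert filter_valid_individuals(two_by_two) == ["a", "b"]

    def test_matches_brute_force_on_random_membership(self, rng):
        sessions = ["s1", "s2", "s3"]
        data = {}
        for j in range(8):
            present = [s for s in sessions if rng.random() < 0.7] or ["s1"]
            data[f"i{j}"] = {s: [rng.normal(size=2)] for s in present}
        ds = make_dataset(data, session_order=sessions)
        expected = sorted(
            ind for ind, per in data.items() if all(s in per for s in sessions)
        )
        if not expected:
            with pytest.raises(EmptyInputError):
                filter_valid_individuals(ds)
        else:
            assert filter_valid_individuals(ds) == expected


class TestClassStatistics:
    def test_identical_samples_have_zero_dispersion(self):
        ds = make_dataset({"a": {"s1": [[1, 2], [1, 2]]}, "b": {"s1": [[0, 0]]}})
        assert intra_class_dispersion(ds, "a") == 0.0

    def test_single_pair_is_its_distance(self):
        ds = make_dataset({"a": {"s1": [[0, 0], [0, 2]]}})
        assert intra_class_dispersion(ds, "a") == pytest.approx(2.0)

    def test_too_few_samples_raises(self):
        ds = make_dataset({"a": {"s1": [[0, 0]]}})
        with pytest.raises(InsufficientSamplesError):
            intra_class_dispersion(ds, "a")

    def test_one_dimensional_inter_class_case(self):
        ds = make_dataset({"a": {"s1": [[0.0]]}, "b": {"s1": [[3.0], [5.0]]}})
        assert mean_inter_class_distance(ds, "a") == pytest.approx(4.0)

    def test_single_individual_raises(self):
        ds = make_dataset({"a": {"s1": [[0.0], [1.0]]}})
        with pytest.raises(InsufficientPopulationError):
            mean_inter_class_distance(ds, "a")

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "spearman"])
    def test_statistics_match_exhaustive_oracle(self, rng, metric):
        ds = random_dataset(rng, 6, dim=5)
        sess = ds.session_order[0]
        for ind in ds.individual_ids:
            own = [r.features for r in ds.samples_of(ind, sess)]
            exp_intra = np.mean(
                [distance(u, v, metric) for u, v in itertools.combinations(own, 2)]
            )
            others = [
                r.features
                for other in ds.individual_ids
                if other != ind
                for r in ds.samples_of(other, sess)
            ]
            exp_inter = np.mean([distance(u, v, metric) for u in own for v in others])
            assert intra_class_dispersion(ds, ind, metric) == pytest.approx(exp_intra)
            assert mean_inter_class_distance(ds, ind, metric) == pytest.approx(exp_inter)


class TestCandidateSelection:
    def test_goats_above_seventieth_percentile_of_ten(self):
        disp = {f"i{k}": float(k) for k in range(1, 11)}
        cands = identify_goats(disp)
        assert [i for i, _ in cands] == ["i8", "i9", "i10"]

    def test_tied_dispersions_break_by_id(self):
        disp = {f"i{k}": 1.0 for k in range(10)}
        cands = identify_goats(disp)
        assert [i for i, _ in cands] == ["i7", "i8", "i9"]

    def test_single_individual_yields_no_goats(self):
        assert identify_goats({"only": 5.0}) == []

    def test_lambs_lower_thirtieth_percentile_of_ten(self):
        sep = {f"i{k}": float(k) for k in range(1, 11)}
        cands = identify_lambs(sep)
        assert [i for i, _ in cands] == ["i1", "i2", "i3", "i4"]

    def test_lamb_count_for_fifty_six(self):
        sep = {f"i{k:02d}": float(k) for k in range(56)}
        assert len(identify_lambs(sep)) == 17

    def test_increasing_separations_select_first_ids(self):
        # N=20, p=30: index 6.5 rounds half-up to 7
        sep = {f"i{k:02d}": float(k) for k in range(20)}
        cands = identify_lambs(sep)
        assert [i for i, _ in cands] == [f"i{k:02d}" for k in range(7)]


class TestFinalizeLabels:
    def _candidates(self, n):
        ids = [f"i{k:02d}" for k in range(n)]
        goats = [(i, 9.0) for i in ids[-17:]]
        lambs = [(i, 0.1) for i in ids[:17]]
        return ids, goats, lambs

    def test_counts_for_fifty_six_individuals(self):
        ids, goats, lambs = self._candidates(56)
        out = finalize_labels(goats, lambs, ids, seed=3)
        assert out.counts() == {"sheep": 44, "goat": 6, "lamb": 6}

    def test_no_goat_candidates_is_not_an_error(self):
        ids = [f"i{k}" for k in range(10)]
        out = finalize_labels([], [(ids[0], 0.0)], ids, seed=0)
        assert out.counts()["goat"] == 0
        assert out.counts()["lamb"] == 1

    def test_overlap_resolved_to_goat(self):
        ids = [f"i{k}" for k in range(10)]
        out = finalize_labels([ids[0]], [ids[0]], ids, seed=0)
        assert out.labels[ids[0]] == "goat"
        assert out.counts()["lamb"] == 0

    def test_same_seed_reproduces_different_seed_varies(self):
        ids, goats, lambs = self._candidates(56)
        a = finalize_labels(goats, lambs, ids, seed=11)
        b = finalize_labels(goats, lambs, ids, seed=11)
        assert a.labels == b.labels
        others = [finalize_labels(goats, lambs, ids, seed=s) for s in range(20)]
        assert any(o.labels != a.labels for o in others)

    def test_labels_partition_valid_ids(self):
        ids, goats, lambs = self._candidates(30)
        out = finalize_labels(goats, lambs, ids, seed=5)
        assert sorted(out.labels) == sorted(ids)
        assert set(out.labels.values()) <= {"sheep", "goat", "lamb"}

    def test_sheep_must_be_majority(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ConstraintViolationError):
            finalize_labels(["a"], ["b"], ids, ZooConfig(final_fraction=0.4), seed=0)


class TestReconcileSharedLabels:
    def _map(self, labels):
        from zoochimera.zoo_labeling import ZooLabelMap

        return ZooLabelMap(labels=dict(labels), goat_candidates=[], lamb_candidates=[])

    def test_full_agreement_is_identity(self):
        labels = {"a": "goat", "b": "lamb", **{f"s{k}": "sheep" for k in range(8)}}
        m = self._map(labels)
        out = reconcile_shared_labels([m, self._map(labels)], seed=1)
        assert out.labels == labels

    def test_divergent_pool_fills_shortfall(self):
        # 30 ids, target = round(0.10*30) = 3 per animal; maps agree on 2 goats
        ids = [f"i{k:02d}" for k in range(30)]
        base = {i: "sheep" for i in ids}
        m1 = dict(base, i00="goat", i01="goat", i02="goat", i10="lamb", i11="lamb", i12="lamb")
        m2 = dict(base, i00="goat", i01="goat", i03="goat", i10="lamb", i11="lamb", i13="lamb")
        out = reconcile_shared_labels([self._map(m1), self._map(m2)], seed=4)
        assert out.labels["i00"] == out.labels["i01"] == "goat"
        counts = out.counts()
        assert counts["goat"] == 3 and counts["lamb"] == 3
        # the extra goat came from the divergent pool
        extra = [i for i in ids if out.labels[i] == "goat" and i not in ("i00", "i01")]
        assert len(extra) == 1 and extra[0] in {"i02", "i03", "i10", "i11", "i12", "i13"}

    def test_same_seed_is_deterministic(self):
        ids = [f"i{k:02d}" for k in range(20)]
        base = {i: "sheep" for i in ids}
        m1 = dict(base, i00="goat", i01="lamb")
        m2 = dict(base, i02="goat", i03="lamb")
        a = reconcile_shared_labels([self._map(m1), self._map(m2)], seed=9)
        b = reconcile_shared_labels([self._map(m1), self._map(m2)], seed=9)
        assert a.labels == b.labels


class TestScaleInvariance:
    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    def test_positive_scaling_preserves_candidates(self, rng, metric):
        ds = random_dataset(rng, 10, dim=4)
        cfg = ZooConfig(metric=metric)
        scaled = make_like = None
        from conftest import make_dataset as _md

        data = {
            ind: {
                sess: [3.7 * r.features for r in ds.samples_of(ind, sess)]
                for sess in ds.session_order
            }
            for ind in ds.individual_ids
        }
        scaled = _md(data, session_order=ds.session_order)
        for d1, d2 in [(ds, scaled)]:
            disp1 = {i: intra_class_dispersion(d1, i, metric) for i in d1.individual_ids}
            disp2 = {i: intra_class_dispersion(d2, i, metric) for i in d2.individual_ids}
            assert [i for i, _ in identify_goats(disp1, cfg)] == [
                i for i, _ in identify_goats(disp2, cfg)
            ]

    def test_monotone_transform_preserves_spearman_candidates(self, rng):
        ds = random_dataset(rng, 8, dim=6)
        cfg = ZooConfig(metric="spearman")
        data = {
            ind: {
                sess: [np.exp(r.features) for r in ds.samples_of(ind, sess)]
                for sess in ds.session_order
            }
            for ind in ds.individual_ids
        }
        warped = make_dataset(data, session_order=ds.session_order)
        d1 = {i: intra_class_dispersion(ds, i, "spearman") for i in ds.individual_ids}
        d2 = {i: intra_class_dispersion(warped, i, "spearman") for i in warped.individual_ids}
        assert [i for i, _ in identify_goats(d1, cfg)] == [i for i, _ in identify_goats(d2, cfg)]


def test_label_modality_discards_and_partitions(rng):
    ds = random_dataset(rng, 12, dim=4)
    # drop one individual's second session to force a discard
    kept = [r for r in ds.records if not (r.individual_id == "i00" and r.session_id == "s2")]
    from zoochimera.modality_store import ModalityDataset

    ds2 = ModalityDataset("m1", ds.dimension, kept, ds.session_order)
    out = label_modality(ds2, seed=1)
    assert out.discarded == ["i00"]
    assert sorted(out.labels) == [f"i{j:02d}" for j in range(1, 12)]
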