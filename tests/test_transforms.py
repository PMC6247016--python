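"""Within-subject temporal transforms against hand values and brute-force oracles."""

import numpy as np
import pytest

from longvol import (
    DistanceMatrix,
    first_differences,
    first_distances,
    from_baseline,
    from_static_reference,
    to_series,
)

from conftest import make_metadata, random_cohort_frame, random_distance_matrix


def _by_subject(series_list):
    return {s.subject_id: s for s in series_list}


def _records(subject, states, values):
    return [
        {"sample-id": f"{subject}.{t:g}", "subject": subject, "state": float(t),
         "value": float(v)}
        for t, v in zip(states, values)
    ]


# --- independent oracles ---------------------------------------------------


def brute_successive_differences(records, grid=None):
    """Per subject: delta at grid state t iff observed at t and its grid
    predecessor; implemented as a flat scan, unlike the library's grouping."""
    if grid is None:
        grid = sorted({r["state"] for r in records})
    lookup = {(r["subject"], r["state"]): r for r in records}
    out = {}
    for r in records:
        t = r["state"]
        k = grid.index(t)
        if k == 0:
            continue
        prev = lookup.get((r["subject"], grid[k - 1]))
        if prev is None:
            continue
        out[r["sample-id"]] = r["value"] - prev["value"]
    return out


def brute_successive_distances(records, dm_ids, dm_values, grid=None):
    index = {sid: k for k, sid in enumerate(dm_ids)}
    records = [r for r in records if r["sample-id"] in index]
    if grid is None:
        grid = sorted({r["state"] for r in records})
    lookup = {(r["subject"], r["state"]): r for r in records}
    out = {}
    for r in records:
        t = r["state"]
        k = grid.index(t)
        if k == 0:
            continue
        prev = lookup.get((r["subject"], grid[k - 1]))
        if prev is None:
            continue
        out[r["sample-id"]] = dm_values[index[r["sample-id"]], index[prev["sample-id"]]]
    return out


def brute_baseline_differences(records, baseline):
    lookup = {(r["subject"], r["state"]): r for r in records}
    out = {}
    for r in records:
        ref = lookup.get((r["subject"], baseline))
        if ref is None or r["state"] == baseline:
            continue
        out[r["sample-id"]] = r["value"] - ref["value"]
    return out


# --- first differences -----------------------------------------------------


class TestFirstDifferences:
    def test_hand_example(self):
        md = make_metadata(_records("S1", [0, 1, 2], [5, 7, 6]))
        (series,) = first_differences(md, "value")
        np.testing.assert_array_equal(series.states, [1.0, 2.0])
        np.testing.assert_array_equal(series.deltas, [2.0, -1.0])
        assert series.sample_ids == ["S1.1", "S1.2"]

    def test_constant_series_all_zero(self):
        md = make_metadata(_records("S1", [0, 1, 2, 3], [3, 3, 3, 3]))
        (series,) = first_differences(md, "value")
        np.testing.assert_array_equal(series.deltas, [0.0, 0.0, 0.0])

    def test_categorical_metric_rejected(self):
        recs = _records("S1", [0, 1], [5, 7])
        for r in recs:
            r["diet"] = "bd"
        md = make_metadata(recs)
        with pytest.raises(ValueError, match="categorical"):
            first_differences(md, "diet")

    def test_single_sample_subject_yields_empty_series(self):
        recs = _records("S1", [0, 1], [5, 7]) + _records("S2", [0], [4])
        series = _by_subject(first_differences(make_metadata(recs), "value"))
        assert len(series["S2"]) == 0
        assert len(series["S1"]) == 1

    def test_matches_bruteforce_on_random_missingness(self):
        rng = np.random.default_rng(42)
        records = random_cohort_frame(rng, n_subjects=200, states=range(8), missing=0.3)
        md = make_metadata(records)
        got = dict(to_series(first_differences(md, "value")))
        assert got == brute_successive_differences(records)

    def test_replicate_policies(self):
        recs = _records("S1", [0, 1], [4.0, 8.0])
        recs.append({"sample-id": "S1.1b", "subject": "S1", "state": 1.0, "value": 2.0})
        md = make_metadata(recs)
        with pytest.raises(ValueError, match="replicate"):
            first_differences(md, "value")
        (dropped,) = first_differences(md, "value", replicate_policy="drop")
        assert len(dropped) == 0  # state 1 removed entirely, no pair remains
        (meaned,) = first_differences(md, "value", replicate_policy="mean")
        np.testing.assert_array_equal(meaned.deltas, [1.0])  # mean(8,2) - 4

    def test_sign_symmetry_under_negation(self):
        rng = np.random.default_rng(3)
        records = random_cohort_frame(rng, n_subjects=30, missing=0.2)
        md = make_metadata(records)
        neg = [dict(r, value=-r["value"]) for r in records]
        md_neg = make_metadata(neg)
        a = to_series(first_differences(md, "value")).sort_index()
        b = to_series(first_differences(md_neg, "value")).sort_index()
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy())

    def test_telescoping_sum_for_gap_free_subjects(self):
        rng = np.random.default_rng(5)
        records = random_cohort_frame(rng, n_subjects=25, missing=0.0)
        md = make_metadata(records)
        values = {r["sample-id"]: r["value"] for r in records}
        for series in first_differences(md, "value"):
            first = values[f"{series.subject_id}.0"]
            last = values[f"{series.subject_id}.4"]
            assert series.deltas.sum() == pytest.approx(last - first)


# --- first distances -------------------------------------------------------


class TestFirstDistances:
    def test_single_pair_lookup(self):
        md = make_metadata(_records("S1", [0, 1], [0, 0]))
        dm = DistanceMatrix(["S1.0", "S1.1"], [[0, 0.42], [0.42, 0]])
        (series,) = first_distances(dm, md)
        np.testing.assert_array_equal(series.deltas, [0.42])
        np.testing.assert_array_equal(series.states, [1.0])

    def test_zero_matrix_gives_zero_deltas(self):
        md = make_metadata(_records("S1", [0, 1, 2], [0, 0, 0]))
        dm = DistanceMatrix(["S1.0", "S1.1", "S1.2"], np.zeros((3, 3)))
        (series,) = first_distances(dm, md)
        np.testing.assert_array_equal(series.deltas, [0.0, 0.0])

    def test_error_when_no_subject_has_two_samples(self):
        md = make_metadata(_records("S1", [0, 1], [0, 0]))
        dm = DistanceMatrix(["S1.0", "other"], [[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="no subject"):
            first_distances(dm, md)

    def test_mean_policy_rejected_in_distance_mode(self):
        md = make_metadata(_records("S1", [0, 1], [0, 0]))
        dm = DistanceMatrix(["S1.0", "S1.1"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="mean"):
            first_distances(dm, md, replicate_policy="mean")

    def test_matches_bruteforce_and_nonnegative(self):
        rng = np.random.default_rng(11)
        records = random_cohort_frame(rng, n_subjects=200, states=range(6), missing=0.25)
        md = make_metadata(records)
        # drop a few samples from the dm to exercise the absent-sample path
        ids = [r["sample-id"] for r in records if rng.random() > 0.05]
        ids, m = random_distance_matrix(rng, ids)
        dm = DistanceMatrix(ids, m)
        series = first_distances(dm, md)
        got = dict(to_series(series))
        assert got == brute_successive_distances(records, ids, dm.values)
        assert all((s.deltas >= 0).all() for s in series)


# --- baseline and static reference -----------------------------------------


class TestBaseline:
    def test_hand_example(self):
        md = make_metadata(_records("S1", [0, 1, 2], [5, 7, 6]))
        (series,) = from_baseline(md, baseline_state=0, metric="value")
        np.testing.assert_array_equal(series.states, [1.0, 2.0])
        np.testing.assert_array_equal(series.deltas, [2.0, 1.0])
        assert series.reference == ("baseline-state", 0.0)

    def test_no_delta_at_baseline_state_itself(self):
        md = make_metadata(_records("S1", [0, 1, 2], [1, 2, 3]))
        dm = DistanceMatrix(["S1.0", "S1.1", "S1.2"],
                            [[0, 0.2, 0.4], [0.2, 0, 0.3], [0.4, 0.3, 0]])
        (series,) = from_baseline(md, baseline_state=0, dm=dm)
        assert 0.0 not in series.states
        np.testing.assert_array_equal(series.deltas, [0.2, 0.4])

    def test_subject_without_baseline_excluded(self):
        recs = _records("S1", [0, 1], [5, 7]) + _records("S2", [1, 2], [4, 6])
        series = from_baseline(make_metadata(recs), baseline_state=0, metric="value")
        assert [s.subject_id for s in series] == ["S1"]

    def test_unobserved_baseline_is_hard_error(self):
        md = make_metadata(_records("S1", [0, 1], [5, 7]))
        with pytest.raises(ValueError, match="baseline"):
            from_baseline(md, baseline_state=9, metric="value")

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(19)
        records = random_cohort_frame(rng, n_subjects=200, states=range(6), missing=0.3)
        # ensure at least one subject has the baseline
        records += _records("Sbase", [0, 1], [1.0, 2.0])
        md = make_metadata(records)
        got = dict(to_series(from_baseline(md, baseline_state=0, metric="value")))
        assert got == brute_baseline_differences(records, 0.0)

    def test_baseline_equals_cumulative_sum_of_successive_deltas(self):
        rng = np.random.default_rng(23)
        records = random_cohort_frame(rng, n_subjects=20, missing=0.0)
        md = make_metadata(records)
        successive = _by_subject(first_differences(md, "value"))
        baseline = _by_subject(from_baseline(md, baseline_state=0, metric="value"))
        for subject, bs in baseline.items():
            np.testing.assert_allclose(bs.deltas, np.cumsum(successive[subject].deltas))


class TestStaticReference:
    def _family(self):
        recs = _records("child1", [0, 1, 2], [0, 0, 0])
        for r in recs:
            r["mother"] = "M1"
        recs2 = _records("child2", [0, 1], [0, 0])
        for r in recs2:
            r["mother"] = ""
        ids = ["child1.0", "child1.1", "child1.2", "child2.0", "child2.1", "M1"]
        m = np.zeros((6, 6))
        for k, d in enumerate([0.9, 0.8, 0.7]):
            m[k, 5] = m[5, k] = d
        return make_metadata(recs + recs2), DistanceMatrix(ids, m)

    def test_child_to_mother_lookup(self):
        md, dm = self._family()
        series = from_static_reference(dm, md, "mother")
        assert [s.subject_id for s in series] == ["child1"]
        np.testing.assert_array_equal(series[0].deltas, [0.9, 0.8, 0.7])
        assert series[0].reference == ("static-sample", "M1")

    def test_all_excluded_is_hard_error(self):
        md, dm = self._family()
        frame = md.frame.copy()
        frame["mother"] = np.nan
        md2 = make_metadata(frame.reset_index().to_dict("records"))
        with pytest.raises(ValueError, match="excluded"):
            from_static_reference(dm, md2, "mother")

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(31)
        records = random_cohort_frame(rng, n_subjects=40, missing=0.2)
        mothers = {f"S{k:03d}": f"M{k:03d}" for k in range(40)}
        for r in records:
            r["mother"] = mothers[r["subject"]]
        ids = [r["sample-id"] for r in records] + list(mothers.values())
        ids, m = random_distance_matrix(rng, ids)
        dm = DistanceMatrix(ids, m)
        md = make_metadata(records)
        got = dict(to_series(from_static_reference(dm, md, "mother")))
        index = {sid: k for k, sid in enumerate(ids)}
        expected = {
            r["sample-id"]: m[index[r["sample-id"]], index[mothers[r["subject"]]]]
            for r in records
        }
        assert got == expected


def test_output_sample_ids_subset_of_input(metadata_factory):
    rng = np.random.default_rng(37)
    records = random_cohort_frame(rng, n_subjects=50, missing=0.4)
    md = metadata_factory(records)
    all_ids = {r["sample-id"] for r in records}
    for series in first_differences(md, "value"):
        assert set(series.sample_ids) <= all_ids
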