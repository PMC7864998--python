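"""Hamming-distance computations and the derived tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import trex
from trex import CompartmentCode as C
from trex.metrics import Scope

from conftest import flat_map, random_labelmap


def _label_grids(shape=(6, 5)):
    return hnp.arrays(np.uint8, shape, elements=st.integers(0, 3))


class TestHamming:
    def test_identical_maps_distance_zero(self, rng):
        m = random_labelmap(rng)
        assert trex.hamming(m, m) == 0.0

    def test_single_pixel_difference(self):
        a = flat_map(100, 200, 300)
        labels = a.labels.copy()
        labels[0, 0] = int(C.RETINA)
        b = trex.CompartmentLabelMap(labels)
        assert trex.hamming(a, b) == pytest.approx(1 / 262144)

    def test_ilm_shift_by_five_rows(self):
        a = flat_map(100, 200, 300)
        b = flat_map(105, 200, 300)
        assert trex.hamming(a, b) == pytest.approx(5 / 512)

    def test_shape_mismatch_rejected(self, rng):
        a = random_labelmap(rng, shape=(4, 4))
        b = random_labelmap(rng, shape=(4, 5))
        with pytest.raises(trex.ValidationError):
            trex.hamming(a, b)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(_label_grids(), _label_grids(), _label_grids())
    def test_metric_axioms(self, ga, gb, gc):
        """Non-negativity, identity of indiscernibles, symmetry, triangle."""
        a, b, c = (trex.CompartmentLabelMap(g) for g in (ga, gb, gc))
        dab = trex.hamming(a, b)
        assert dab >= 0
        assert (dab == 0) == np.array_equal(a.labels, b.labels)
        assert dab == trex.hamming(b, a)
        assert dab <= trex.hamming(a, c) + trex.hamming(c, b) + 1e-15

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(_label_grids(), _label_grids())
    def test_compartment_sum_is_twice_overall(self, ga, gb):
        """Each differing pixel flips exactly two binary maps."""
        a, b = trex.CompartmentLabelMap(ga), trex.CompartmentLabelMap(gb)
        total = sum(trex.compartment_hamming(a, b, c) for c in C)
        assert total == pytest.approx(2 * trex.hamming(a, b))

    def test_pixel_permutation_equivariance(self, rng):
        a = random_labelmap(rng, shape=(10, 9))
        b = random_labelmap(rng, shape=(10, 9))
        perm = rng.permutation(a.labels.size)
        pa = trex.CompartmentLabelMap(a.labels.ravel()[perm].reshape(a.shape))
        pb = trex.CompartmentLabelMap(b.labels.ravel()[perm].reshape(b.shape))
        assert trex.hamming(pa, pb) == trex.hamming(a, b)
        for c in C:
            assert trex.compartment_hamming(pa, pb, c) == trex.compartment_hamming(a, b, c)


class TestCompartmentHamming:
    def test_ilm_shift_per_compartment(self):
        a = flat_map(100, 200, 300)
        b = flat_map(105, 200, 300)
        expected = {C.VITREOUS: 5 / 512, C.RETINA: 5 / 512, C.CHOROID: 0.0, C.SCLERA: 0.0}
        for c, value in expected.items():
            assert trex.compartment_hamming(a, b, c) == pytest.approx(value)

    def test_complement_case(self):
        a = trex.CompartmentLabelMap(np.full((4, 4), int(C.RETINA)))
        b = trex.CompartmentLabelMap(np.full((4, 4), int(C.SCLERA)))
        assert trex.compartment_hamming(a, b, C.RETINA) == 1.0
        assert trex.compartment_hamming(a, b, C.VITREOUS) == 0.0


def _toy_ensemble(rng, grader_ids, n_scans, shape=(8, 8), model_id=None):
    ens = trex.GradingEnsemble(grader_ids=list(grader_ids), model_id=model_id)
    for s in range(n_scans):
        for g in ens.grading_ids:
            ens.add(trex.CompartmentLabelMap(
                rng.integers(0, 4, shape), f"s{s}", g
            ))
    return ens


class TestDistanceTable:
    def test_record_counts_two_gradings(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2"], 3)
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        assert len(table) == 3

    def test_record_counts_full_design(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2", "g3"], 10, model_id="cnn")
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        assert len(table) == 60  # 6 pairs x 10 scans

    def test_missing_map_error_names_it(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2"], 2)
        del ens.maps[("s1", "g2")]
        with pytest.raises(trex.ValidationError, match="s1.*g2"):
            trex.build_distance_table(ens)

    def test_zero_noise_scene_matches_analytic_offsets(self):
        """Flat boundaries with constant per-boundary offsets give exactly
        hamming = sum(|offset|)/H when the shifted bands do not overlap."""
        h = w = 64
        ens = trex.GradingEnsemble(grader_ids=["g1", "g2"])
        offsets = (2.0, -3.0, 4.0)
        for s in range(3):
            base = (20.0 + s, 35.0 + s, 50.0 + s)
            ens.add(flat_map(*base, height=h, width=w, scan_id=f"s{s}", grading_id="g1"))
            shifted = tuple(r + o for r, o in zip(base, offsets))
            ens.add(flat_map(*shifted, height=h, width=w, scan_id=f"s{s}", grading_id="g2"))
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        expected = sum(abs(o) for o in offsets) / h
        assert np.allclose(table.frame["distance"], expected)

    def test_table_sum_identity_per_record(self, small_study):
        _, _, ensemble, _ = small_study
        table = trex.build_distance_table(ensemble)
        wide = table.frame.pivot_table(
            index=["scan_id", "grading_a", "grading_b"], columns="scope",
            values="distance",
        )
        comp = wide[[s.value for s in Scope if s is not Scope.ALL]].sum(axis=1)
        assert np.allclose(comp, 2 * wide["all"])

    def test_csv_round_trip(self, rng, tmp_path):
        ens = _toy_ensemble(rng, ["g1", "g2"], 3)
        table = trex.build_distance_table(ens)
        path = tmp_path / "d.csv"
        table.to_csv(path)
        back = trex.DistanceTable.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, table.frame)


class TestMeanDistanceMatrix:
    def test_single_scan_matrix_equals_that_scans_distances(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2", "g3"], 1)
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        mat = trex.mean_distance_matrix(table, Scope.ALL)
        for _, row in table.frame.iterrows():
            assert mat.entry(row["grading_a"], row["grading_b"]) == row["distance"]

    def test_random_fixture_matches_brute_force_mean(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2", "g3"], 5, model_id="cnn")
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        mat = trex.mean_distance_matrix(table, Scope.ALL)
        for a, b in table.pairs:
            rows = table.select(Scope.ALL, (a, b))
            assert mat.entry(a, b) == pytest.approx(rows["distance"].mean())

    def test_matrix_is_metric_when_scanwise_metric(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2", "g3", "g4"], 6)
        mat = trex.mean_distance_matrix(
            trex.build_distance_table(ens, scopes=[Scope.ALL]), Scope.ALL
        )
        v = mat.values
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-12

    def test_unequal_scan_sets_rejected(self, rng):
        ens = _toy_ensemble(rng, ["g1", "g2", "g3"], 3)
        table = trex.build_distance_table(ens, scopes=[Scope.ALL])
        frame = table.frame[
            ~((table.frame["scan_id"] == "s0")
              & (table.frame["grading_a"] == "g1")
              & (table.frame["grading_b"] == "g2"))
        ]
        with pytest.raises(trex.ValidationError, match="scan sets"):
            trex.mean_distance_matrix(trex.DistanceTable(frame), Scope.ALL)


def _table_from_values(values):
    """values: {scan: {pair: d}} at scope ALL."""
    rows = [
        (scan, a, b, "all", d)
        for scan, pairs in values.items()
        for (a, b), d in pairs.items()
    ]
    return trex.DistanceTable(
        pd.DataFrame(rows, columns=["scan_id", "grading_a", "grading_b", "scope", "distance"])
    )


class TestFractionModelCloser:
    def test_hand_evaluated_toy_table(self):
        per_scan = [(0.01, 0.02), (0.03, 0.02), (0.01, 0.05)]
        values = {}
        for i, (model_mean, grader_mean) in enumerate(per_scan):
            values[f"s{i}"] = {
                ("g1", "g2"): grader_mean, ("g1", "g3"): grader_mean,
                ("g2", "g3"): grader_mean,
                ("g1", "cnn"): model_mean, ("g2", "cnn"): model_mean,
                ("g3", "cnn"): model_mean,
            }
        frac = trex.fraction_model_closer(
            _table_from_values(values), ["g1", "g2", "g3"], "cnn"
        )
        assert frac == pytest.approx(2 / 3)

    def test_ties_count_as_not_closer(self):
        values = {"s0": {
            ("g1", "g2"): 0.02, ("g1", "g3"): 0.02, ("g2", "g3"): 0.02,
            ("g1", "cnn"): 0.02, ("g2", "cnn"): 0.02, ("g3", "cnn"): 0.02,
        }}
        assert trex.fraction_model_closer(
            _table_from_values(values), ["g1", "g2", "g3"], "cnn"
        ) == 0.0

    def test_model_identical_to_one_grader(self):
        # model == g1 -> per scan: mean(0, d12, d13) < mean(d12, d13, d23)
        # iff d23 > 0
        values = {"s0": {
            ("g1", "g2"): 0.1, ("g1", "g3"): 0.2, ("g2", "g3"): 0.15,
            ("g1", "cnn"): 0.0, ("g2", "cnn"): 0.1, ("g3", "cnn"): 0.2,
        }}
        assert trex.fraction_model_closer(
            _table_from_values(values), ["g1", "g2", "g3"], "cnn"
        ) == 1.0

    def test_incomplete_records_rejected(self):
        values = {"s0": {
            ("g1", "g2"): 0.1, ("g1", "g3"): 0.2, ("g2", "g3"): 0.15,
            ("g1", "cnn"): 0.0, ("g2", "cnn"): 0.1,
        }}
        with pytest.raises(trex.ValidationError):
            trex.fraction_model_closer(
                _table_from_values(values), ["g1", "g2", "g3"], "cnn"
            )
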