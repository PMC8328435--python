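"""Capture-recapture: history validation, m-arrays, cell probabilities,
and the multinomial likelihood against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eider_ipm.cmr import (
    CaptureHistory,
    adult_cell_probabilities,
    build_marray,
    build_marrays,
    cmr_loglik,
    duckling_cell_probabilities,
    read_capture_histories,
)

from conftest import enumerate_duckling_paths, forward_history_loglik, make_history


class TestCaptureHistoryValidation:
    def test_adult_history_round_trip(self):
        h = make_history("adult", "1001")
        assert h.first_index == 0
        assert h.detections.tolist() == [1, 0, 0, 1]

    def test_duckling_detected_next_year_rejected(self):
        with pytest.raises(ValueError, match="unobservable"):
            make_history("duckling", "1100")

    def test_detection_before_first_year_rejected(self):
        years = np.arange(2000, 2004)
        with pytest.raises(ValueError, match="before first_year"):
            CaptureHistory(
                id="x", cohort="adult", first_year=2002, years=years,
                detections=np.array([1, 0, 1, 0]),
            )

    def test_missing_release_detection_rejected(self):
        years = np.arange(2000, 2004)
        with pytest.raises(ValueError, match="first_year"):
            CaptureHistory(
                id="x", cohort="adult", first_year=2000, years=years,
                detections=np.array([0, 0, 1, 0]),
            )

    def test_reader_parses_and_validates(self, tmp_path):
        path = tmp_path / "cap.csv"
        path.write_text(
            "id,cohort,first_year,2000,2001,2002,2003\n"
            "a1,adult,2000,1,0,0,1\n"
            "d1,duckling,2000,1,0,1,0\n"
        )
        hs = read_capture_histories(path)
        assert len(hs) == 2
        assert hs[1].cohort == "duckling"

    def test_reader_rejects_invalid_duckling_with_line_number(self, tmp_path):
        path = tmp_path / "cap.csv"
        path.write_text(
            "id,cohort,first_year,2000,2001,2002\n" "d1,duckling,2000,1,1,0\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_capture_histories(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "cap.csv"
        path.write_text("id,cohort,first_year,2000,2001\n")
        with caplog.at_level("WARNING"):
            assert read_capture_histories(path) == []
        assert "no records" in caplog.text


class TestMArray:
    def test_hand_enumerated_adult_marray(self):
        hs = [make_history("adult", s) for s in ("1011", "1100", "1000")]
        ma = build_marray(hs, "adult")
        assert ma.releases.tolist() == [3, 1, 1]
        assert ma.m[0, 1] == 1 and ma.m[0, 2] == 1 and ma.never[0] == 1
        assert ma.m[1].sum() == 0 and ma.never[1] == 1
        assert ma.m[2, 3] == 1 and ma.never[2] == 0

    def test_single_unrecaptured_history(self):
        ma = build_marray([make_history("adult", "1000")], "adult")
        assert ma.never[0] == 1 and ma.m.sum() == 0

    def test_duckling_rereleases_enter_adult_array(self):
        # duckling caught at +2 then +3: one duckling cell, one adult cell
        hs = [make_history("duckling", "10110")]
        ms = build_marrays(hs)
        assert ms.duckling.m[0, 2] == 1
        assert ms.duckling.releases.tolist() == [1, 0, 0, 0]
        assert ms.adult.m[2, 3] == 1
        assert ms.adult.releases[2] == 1 and ms.adult.releases[3] == 1
        assert ms.adult.never[3] == 1  # re-released at +3, never seen again

    def test_final_occasion_release_carries_no_row(self):
        hs = [make_history("adult", "0001")]
        ms = build_marrays(hs)
        assert ms.adult.releases.sum() == 0

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_row_sums_reproduce_release_counts(self, data):
        n_occ = data.draw(st.integers(4, 8))
        n_ind = data.draw(st.integers(1, 12))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        hs = []
        for i in range(n_ind):
            cohort = rng.choice(["adult", "duckling"])
            first = int(rng.integers(0, n_occ - 1))
            det = np.zeros(n_occ, dtype=int)
            det[first] = 1
            start = first + 2 if cohort == "duckling" else first + 1
            for occ in range(start, n_occ):
                det[occ] = int(rng.random() < 0.4)
            hs.append(
                CaptureHistory(
                    id=str(i), cohort=str(cohort), first_year=2000 + first,
                    years=np.arange(2000, 2000 + n_occ), detections=det,
                )
            )
        ms = build_marrays(hs, n_occ)
        ms.validate()  # row sums == releases, by construction check
        total_detections = sum(h.detections.sum() - 1 for h in hs)
        assert ms.duckling.m.sum() + ms.adult.m.sum() == total_detections


class TestCellProbabilities:
    def test_adult_constant_parameter_cells(self):
        phi = np.full(5, 0.8)
        p = np.full(5, 0.5)
        cells, never = adult_cell_probabilities(phi, p)
        assert cells[0, 1] == pytest.approx(0.40)
        assert cells[0, 2] == pytest.approx(0.16)
        assert np.allclose(cells.sum(axis=1) + never, 1.0)

    def test_adult_degenerate_detection(self):
        cells, never = adult_cell_probabilities(np.full(4, 0.9), np.zeros(4))
        assert np.all(cells == 0) and np.allclose(never, 1.0)
        cells, _ = adult_cell_probabilities(np.ones(4), np.ones(4))
        assert cells[0, 1] == 1.0 and np.all(cells[0, 2:] == 0)

    def test_duckling_published_example_cells(self):
        phi_j = np.full(6, 0.5)
        phi_a = np.full(6, 0.8)
        p = np.full(6, 0.5)
        cells, never = duckling_cell_probabilities(phi_j, phi_a, 0.5, p)
        assert cells[0, 1] == 0.0  # 1-year-olds unobservable
        assert cells[0, 2] == pytest.approx(0.10)
        assert cells[0, 3] == pytest.approx(0.12)
        assert cells[0, 4] == pytest.approx(0.048)
        assert np.allclose(cells.sum(axis=1) + never, 1.0)

    def test_duckling_alpha_one_collapses_to_delayed_cjs(self):
        phi_j, phi_a, p = np.full(5, 0.5), np.full(5, 0.8), np.full(5, 0.5)
        cells, _ = duckling_cell_probabilities(phi_j, phi_a, 1.0, p)
        assert cells[0, 2] == pytest.approx(0.5 * 0.8 * 0.5)

    def test_duckling_no_detection_means_never_seen(self):
        cells, never = duckling_cell_probabilities(
            np.full(5, 0.5), np.full(5, 0.8), 0.5, np.zeros(5)
        )
        assert np.all(cells == 0) and np.allclose(never, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_duckling_cells_match_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_occ = 6
        phi_j = rng.uniform(0.2, 0.8, n_occ - 1)
        phi_a = rng.uniform(0.5, 0.95, n_occ - 1)
        p = rng.uniform(0.2, 0.9, n_occ - 1)
        alpha = rng.uniform(0.1, 0.9)
        cells, never = duckling_cell_probabilities(phi_j, phi_a, alpha, p)
        for t in range(n_occ - 1):
            oc, on = enumerate_duckling_paths(phi_j, phi_a, alpha, p, t, n_occ)
            assert cells[t] == pytest.approx(oc, rel=1e-12, abs=1e-15)
            assert never[t] == pytest.approx(on, rel=1e-12)

    def test_rows_partition_probability_one(self):
        rng = np.random.default_rng(99)
        phi_j = rng.uniform(0.1, 0.9, 8)
        phi_a = rng.uniform(0.1, 0.9, 8)
        p = rng.uniform(0.1, 0.9, 8)
        cells, never = duckling_cell_probabilities(phi_j, phi_a, 0.4, p)
        assert np.allclose(cells.sum(axis=1) + never, 1.0, atol=1e-12)


class TestCmrLoglik:
    def test_empty_marray_is_zero(self):
        hs = [make_history("adult", "1000")]
        ma = build_marray(hs, "duckling")  # no duckling histories
        phi = np.full(3, 0.8)
        p = np.full(3, 0.5)
        cells, never = duckling_cell_probabilities(phi, phi, 0.5, p)
        assert cmr_loglik(ma, cells, never) == 0.0

    def test_all_never_seen_with_zero_detection_is_certain(self):
        hs = [make_history("adult", "1000"), make_history("adult", "1000")]
        ma = build_marray(hs, "adult")
        cells, never = adult_cell_probabilities(np.full(3, 0.8), np.zeros(3))
        assert cmr_loglik(ma, cells, never) == 0.0

    def test_positive_count_on_zero_cell_is_minus_inf(self):
        hs = [make_history("adult", "1100")]
        ma = build_marray(hs, "adult")
        cells, never = adult_cell_probabilities(np.full(3, 0.8), np.zeros(3))
        assert cmr_loglik(ma, cells, never) == -np.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_marray_loglik_equals_per_history_oracle(self, seed):
        """m-array multinomial likelihood == product of exact per-history
        forward-sum likelihoods, random histories and parameters."""
        rng = np.random.default_rng(seed)
        n_occ = int(rng.integers(4, 7))
        n_ind = int(rng.integers(4, 11))
        phi_j = rng.uniform(0.2, 0.8, n_occ - 1)
        phi_a = rng.uniform(0.4, 0.95, n_occ - 1)
        p = rng.uniform(0.2, 0.9, n_occ - 1)
        alpha = rng.uniform(0.1, 0.9)
        hs = []
        years = np.arange(2000, 2000 + n_occ)
        for i in range(n_ind):
            cohort = str(rng.choice(["adult", "duckling"]))
            first = int(rng.integers(0, n_occ - 2))
            det = np.zeros(n_occ, dtype=int)
            det[first] = 1
            start = first + 2 if cohort == "duckling" else first + 1
            for occ in range(start, n_occ):
                det[occ] = int(rng.random() < 0.5)
            hs.append(
                CaptureHistory(
                    id=str(i), cohort=cohort, first_year=2000 + first,
                    years=years, detections=det,
                )
            )
        ms = build_marrays(hs, n_occ)
        ca, na = adult_cell_probabilities(phi_a, p)
        cd, nd = duckling_cell_probabilities(phi_j, phi_a, alpha, p)
        ll_marray = cmr_loglik(ms.adult, ca, na) + cmr_loglik(ms.duckling, cd, nd)
        ll_oracle = sum(
            forward_history_loglik(h, phi_j, phi_a, alpha, p) for h in hs
        )
        assert ll_marray == pytest.approx(ll_oracle, rel=1e-11)
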