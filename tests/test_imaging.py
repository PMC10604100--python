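"""Pore-array image analysis: localization, trace extraction, classification,
occupancy statistics and wide-field/TIRF comparison."""

import numpy as np
import pandas as pd
import pytest

from zmwell import (
    SimConfig,
    classify_pores,
    detect_pores,
    extract_pore_traces,
    make_cell_movie,
    make_layout,
    occupancy_by_size,
    wf_tirf_compare,
)
from zmwell.imaging import RegistrationError, switching_score


def _controls(traces, truth):
    covered = truth.set_index("pore_id")["covered"]
    return [t for t in traces if not covered.loc[t.pore_id]]


class TestDetection:
    def test_all_pores_found_subpixel(self, default_movie):
        layout = default_movie["layout"]
        centers = detect_pores(default_movie["brightfield"], layout)
        assert len(centers) == len(layout.pores)
        assert not centers["missing"].any()
        err = np.hypot(
            centers["x_px"] - layout.pores["x_px"],
            centers["y_px"] - layout.pores["y_px"],
        )
        assert err.max() < 0.5

    def test_blank_image_raises(self, default_movie):
        layout = default_movie["layout"]
        with pytest.raises(RegistrationError):
            detect_pores(np.zeros(layout.shape), layout)

    def test_translation_equivariance(self, default_movie):
        layout = default_movie["layout"]
        bf = default_movie["brightfield"]
        shifted = np.roll(np.roll(bf, 3, axis=0), -2, axis=1)
        c0 = detect_pores(bf, layout)
        c1 = detect_pores(shifted, layout)
        inner = ~c0["missing"] & ~c1["missing"]
        dx = (c1["x_px"] - c0["x_px"])[inner]
        dy = (c1["y_px"] - c0["y_px"])[inner]
        assert np.median(dx) == pytest.approx(-2.0, abs=0.2)
        assert np.median(dy) == pytest.approx(3.0, abs=0.2)

    def test_too_few_markers_rejected(self, default_movie):
        from zmwell.synthetic import PoreArrayLayout

        layout = default_movie["layout"]
        bad = PoreArrayLayout(
            pores=layout.pores,
            markers=layout.markers.iloc[:2],
            pixel_nm=layout.pixel_nm,
            shape=layout.shape,
        )
        with pytest.raises(RegistrationError):
            detect_pores(default_movie["brightfield"], bad)


class TestTraceExtraction:
    def test_uniform_image_gives_zero(self):
        movie = np.full((5, 40, 40), 123.4)
        centers = pd.DataFrame(
            {"pore_id": [0], "x_px": [20.0], "y_px": [20.0],
             "d_nm": [200.0], "h_nm": [100.0]}
        )
        traces = extract_pore_traces(movie, centers)
        assert np.allclose(traces[0].values, 0.0)

    def test_offset_invariance(self, default_movie):
        layout = default_movie["layout"]
        centers = layout.pores.copy()
        t0 = extract_pore_traces(default_movie["channel1"], centers)
        t1 = extract_pore_traces(default_movie["channel1"] + 500.0, centers)
        for a, b in zip(t0, t1):
            # exact up to float32 rounding of the stored frames
            assert np.allclose(a.values, b.values, atol=1e-3)

    def test_inserted_amplitude_forward_model(self):
        """A point amplitude A in the window center recovers
        A * (1 - 49/24 * ring_fraction) per the window arithmetic."""
        movie = np.full((3, 41, 41), 10.0)
        movie[:, 20, 20] += 490.0  # single bright pixel, A = 490
        centers = pd.DataFrame(
            {"pore_id": [0], "x_px": [20.0], "y_px": [20.0],
             "d_nm": [0.0], "h_nm": [0.0]}
        )
        tr = extract_pore_traces(movie, centers)[0]
        # inner mean includes A/49; ring excludes the center pixel
        assert np.allclose(tr.values, 490.0 / 49.0)

    def test_border_pores_excluded_with_warning(self):
        movie = np.zeros((2, 30, 30))
        centers = pd.DataFrame(
            {"pore_id": [0, 1], "x_px": [1.0, 15.0], "y_px": [1.0, 15.0],
             "d_nm": [0.0, 0.0], "h_nm": [0.0, 0.0]}
        )
        with pytest.warns(UserWarning, match="border"):
            traces = extract_pore_traces(movie, centers)
        assert [t.pore_id for t in traces] == [1]


class TestClassification:
    def test_accuracy_against_ground_truth(self):
        layout = make_layout()
        accs = []
        for seed in range(5):
            mov = make_cell_movie(layout, SimConfig(seed=seed), n_frames=30)
            centers = detect_pores(mov["brightfield"], layout)
            traces = extract_pore_traces(mov["channel1"], centers)
            classes, _ = classify_pores(
                traces, _controls(traces, mov["truth"])
            )
            merged = classes.merge(
                mov["truth"][["pore_id", "population_realized"]], on="pore_id"
            )
            accs.append(
                (merged["label"] == merged["population_realized"]).mean()
            )
        assert np.mean(accs) >= 0.98

    def test_all_control_input_gives_no_positives(self):
        layout = make_layout()
        mov = make_cell_movie(
            layout, SimConfig(seed=3, covered_fraction=0.0), n_frames=20
        )
        traces = extract_pore_traces(mov["channel1"], layout.pores)
        classes, _ = classify_pores(traces, traces)
        assert (classes["label"] == "negative").all()

    def test_missing_controls_rejected(self, default_movie):
        traces = extract_pore_traces(
            default_movie["channel1"], default_movie["layout"].pores
        )
        with pytest.raises(ValueError, match="control"):
            classify_pores(traces, [])

    def test_switching_score_archetypes(self, rng):
        flat = rng.normal(100.0, 5.0, 200)
        telegraph = np.where(
            np.repeat(np.arange(10) % 2, 20), 100.0, 0.0
        ) + rng.normal(0, 5.0, 200)
        assert switching_score(flat) < 3.0
        assert switching_score(telegraph) > 10.0
        assert switching_score(np.full(100, 3.0)) == 0.0


class TestOccupancy:
    def _classes(self, labels, d=200.0, h=100.0):
        return pd.DataFrame(
            {
                "pore_id": np.arange(len(labels)),
                "d_nm": d,
                "h_nm": h,
                "label": labels,
            }
        )

    def test_all_positive(self):
        occ = occupancy_by_size(self._classes(["high"] * 10))
        assert occ["fraction"].iloc[0] == 1.0

    def test_none_positive(self):
        occ = occupancy_by_size(self._classes(["negative"] * 10))
        assert occ["fraction"].iloc[0] == 0.0

    def test_half_positive_with_ci(self):
        occ = occupancy_by_size(
            self._classes(["high", "negative"] * 100)
        )
        assert occ["fraction"].iloc[0] == pytest.approx(0.5)
        assert occ["ci_low"].iloc[0] < 0.5 < occ["ci_high"].iloc[0]
        assert occ["ci_high"].iloc[0] - occ["ci_low"].iloc[0] < 0.2


class TestWfTirf:
    def _run(self, seed=4, low_scale=1.0):
        layout = make_layout()
        cfg = SimConfig(seed=seed, switching_fraction=0.0)
        return layout, make_cell_movie(
            layout, cfg, n_frames=30, low_scale=low_scale
        )

    def test_identical_inputs_ratio_one(self):
        layout, mov = self._run()
        traces = extract_pore_traces(mov["channel1"], layout.pores)
        classes, _ = classify_pores(traces, _controls(traces, mov["truth"]))
        cmp = wf_tirf_compare(traces, traces, classes)
        filled = cmp[~cmp["empty"]]
        assert np.allclose(filled["ratio_tirf_wf"], 1.0)

    def test_low_class_dimming_recovered(self):
        layout, mov_wf = self._run(seed=4, low_scale=1.0)
        _, mov_tirf = self._run(seed=4, low_scale=0.5)
        tr_wf = extract_pore_traces(mov_wf["channel1"], layout.pores)
        tr_tirf = extract_pore_traces(mov_tirf["channel1"], layout.pores)
        classes, _ = classify_pores(tr_wf, _controls(tr_wf, mov_wf["truth"]))
        cmp = wf_tirf_compare(tr_wf, tr_tirf, classes).set_index("label")
        assert cmp.loc["low", "ratio_tirf_wf"] == pytest.approx(0.5, abs=0.1)
        assert cmp.loc["high", "ratio_tirf_wf"] == pytest.approx(1.0, abs=0.05)

    def test_unmatched_pore_sets_rejected(self):
        layout, mov = self._run()
        traces = extract_pore_traces(mov["channel1"], layout.pores)
        classes, _ = classify_pores(traces, _controls(traces, mov["truth"]))
        with pytest.raises(ValueError, match="match"):
            wf_tirf_compare(traces, traces[:-1], classes)

    def test_empty_class_flagged(self):
        layout, mov = self._run()
        traces = extract_pore_traces(mov["channel1"], layout.pores)
        classes, _ = classify_pores(traces, _controls(traces, mov["truth"]))
        classes.loc[classes["label"] == "low", "label"] = "high"
        cmp = wf_tirf_compare(traces, traces, classes).set_index("label")
        assert cmp.loc["low", "empty"]
        assert np.isnan(cmp.loc["low", "ratio_tirf_wf"])
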