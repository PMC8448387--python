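"""dF/F normalisation, recruitment calls, rings, and wave metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calwave.config import SimulationConfig
from calwave.pipeline import analyze_movie
from calwave.synthetic import simulate_movie
from calwave.wave import (DeadROIError, Movie, RecruitmentCall, ROISet,
                          assign_ring, basal_fluorescence, classify_recruited,
                          detect_rois, dff_trace, transient_auc, wave_metrics,
                          wave_speed)


def _movie_from_frames(frames, **kw):
    kw.setdefault("frame_interval", 1.0)
    kw.setdefault("pixel_size", 1.0)
    kw.setdefault("stim_frame", 15)
    kw.setdefault("stim_site", (0.0, 0.0))
    return Movie(frames=np.asarray(frames, dtype=float), **kw)


class TestBasalFluorescence:
    def test_constant_movie(self):
        m = _movie_from_frames(np.full((30, 4, 4), 7.0))
        assert np.all(basal_fluorescence(m) == 7.0)

    def test_ramp_mean(self):
        frames = np.zeros((30, 1, 1))
        frames[:15, 0, 0] = np.arange(1, 16)
        m = _movie_from_frames(frames)
        assert basal_fluorescence(m)[0, 0] == 8.0

    def test_default_window_is_the_prestimulus_window(self):
        frames = np.random.default_rng(0).normal(100, 1, (40, 3, 3))
        m = _movie_from_frames(frames, stim_frame=15)
        assert np.allclose(basal_fluorescence(m), frames[:15].mean(axis=0))

    def test_empty_window_rejected(self):
        m = _movie_from_frames(np.ones((30, 2, 2)))
        with pytest.raises(ValueError):
            basal_fluorescence(m, pre_frames=0)


class TestDffTrace:
    def test_identity_baseline_gives_zero(self):
        assert np.all(dff_trace(np.full(10, 3.0), 3.0) == 0.0)

    def test_doubling_gives_one(self):
        out = dff_trace(np.array([5.0, 10.0, 5.0]), 5.0)
        assert out[1] == 1.0

    def test_dead_roi_rejected(self):
        with pytest.raises(DeadROIError):
            dff_trace(np.ones(5), 0.0)


@pytest.mark.parametrize("dist_um,ring", [(0.0, 0), (49.999, 0), (50.0, 1),
                                          (125.0, 2), (300.0, 6)])
def test_ring_assignment_half_open(dist_um, ring):
    d, k = assign_ring((dist_um / 2.0, 0.0), (0.0, 0.0), pixel_size=2.0)
    assert d == pytest.approx(dist_um)
    assert k == ring


class TestClassifyRecruited:
    def _trace(self, n=60, stim=15):
        rng = np.random.default_rng(0)
        return rng.normal(0, 0.01, n), stim

    def test_flat_trace_not_recruited(self):
        dff, stim = self._trace()
        rec, act = classify_recruited(dff, stim)
        assert not rec and act is None

    def test_first_sustained_crossing_is_activation_frame(self):
        dff, stim = self._trace()
        dff[17:25] += 1.0
        rec, act = classify_recruited(dff, stim, min_frames=2)
        assert rec and act == 17

    def test_prestimulus_activity_is_excluded(self):
        dff, stim = self._trace()
        dff[5:9] += 1.0
        rec, act = classify_recruited(dff, stim)
        assert not rec

    def test_zero_variance_prestim_falls_back_to_floor(self):
        dff = np.zeros(60)
        dff[20:30] = 0.5
        rec, act = classify_recruited(dff, 15, dff_floor=0.2)
        assert rec and act == 20

    def test_brief_blip_shorter_than_min_frames_ignored(self):
        dff, stim = self._trace()
        dff[20] += 1.0
        rec, _ = classify_recruited(dff, stim, min_frames=2)
        assert not rec


class TestTransientAuc:
    def test_constant_one_ten_samples(self):
        assert transient_auc(np.ones(10), (0, 10), 1.0) == pytest.approx(9.0)

    def test_zero_trace(self):
        assert transient_auc(np.zeros(10), (0, 10), 1.0) == 0.0

    def test_triangle(self):
        assert transient_auc(np.array([0.0, 1.0, 0.0]), (0, 3), 1.0) == \
            pytest.approx(1.0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            transient_auc(np.ones(10), (3, 4), 1.0)


def _call(i, dist, frame, recruited=True, amp=1.0):
    return RecruitmentCall(roi_id=i, recruited=recruited,
                           activation_frame=frame, peak_amplitude=amp,
                           peak_dff=amp / 100, distance=dist,
                           ring_index=int(dist // 50))


class TestWaveMetrics:
    def test_speed_formula(self):
        assert wave_speed(300.0, 16.0, 26.0) == pytest.approx(30.0)
        assert np.isnan(wave_speed(300.0, 20.0, 20.0))

    def test_single_cell_speed_undefined(self):
        with pytest.warns(UserWarning):
            m = wave_metrics([_call(0, 120.0, 20)], 1.0)
        assert m.max_length == 120.0
        assert np.isnan(m.speed)
        assert m.total_recruited == 1

    def test_no_recruited_cells_is_na_with_warning(self):
        with pytest.warns(UserWarning):
            m = wave_metrics([_call(0, 10.0, None, recruited=False)], 1.0)
        assert m.total_recruited == 0 and np.isnan(m.max_length)

    def test_direct_formula(self):
        calls = [_call(0, 10.0, 16), _call(1, 300.0, 26)]
        m = wave_metrics(calls, 1.0)
        assert m.t0 == 16.0 and m.t1 == 26.0
        assert m.speed == pytest.approx(30.0)

    def test_tie_break_takes_earliest_at_max_length(self):
        calls = [_call(0, 10.0, 16), _call(1, 200.0, 30), _call(2, 200.0, 24)]
        m = wave_metrics(calls, 1.0)
        assert m.t1 == 24.0

    def test_brute_force_oracle_equivalence(self, small_movie, small_config):
        """wave_metrics agrees with explicit max/argmax over the truth table."""
        _, tr = small_movie
        rec = tr[tr.recruited]
        dt = small_config.frame_interval
        calls = [_call(r.cell_id, r.distance,
                       int(np.ceil((small_config.stim_onset
                                    + r.activation_time) / dt)),
                       amp=r.peak_amplitude)
                 for r in rec.itertuples()]
        m = wave_metrics(calls, dt)
        # independent recomputation straight off the table
        times = {c.roi_id: c.activation_frame * dt for c in calls}
        exp_max = rec.distance.max()
        exp_t0 = min(times.values())
        at_max = [c.roi_id for c in calls if c.distance == exp_max]
        exp_t1 = min(times[i] for i in at_max)
        assert m.max_length == pytest.approx(exp_max)
        assert m.t0 == exp_t0 and m.t1 == exp_t1
        assert m.speed == pytest.approx(exp_max / (exp_t1 - exp_t0))
        assert m.total_recruited == len(rec)
        assert sum(m.cells_per_ring) == m.total_recruited
        assert m.mean_amplitude == pytest.approx(rec.peak_amplitude.mean())

    def test_adding_a_cell_never_decreases_max_length(self):
        calls = [_call(0, 80.0, 18), _call(1, 140.0, 21)]
        base = wave_metrics(calls, 1.0).max_length
        grown = wave_metrics(calls + [_call(2, 60.0, 17)], 1.0).max_length
        assert grown >= base
        assert wave_metrics(calls + [_call(3, 200.0, 25)], 1.0).max_length >= base


@settings(max_examples=20, deadline=None, derandomize=True)
@given(c=st.floats(min_value=0.05, max_value=50.0,
                   allow_nan=False, allow_infinity=False))
def test_scale_equivariance_of_dff(c):
    """dF/F is invariant to rescaling all raw intensities by c > 0."""
    rng = np.random.default_rng(3)
    raw = rng.normal(100, 2, 60)
    raw[20:30] += 40
    fb = raw[:15].mean()
    d1 = dff_trace(raw, fb)
    d2 = dff_trace(c * raw, c * fb)
    assert np.allclose(d1, d2)


def test_scale_equivariance_end_to_end(small_movie):
    movie, _ = small_movie
    scaled = Movie(frames=3.7 * movie.frames,
                   frame_interval=movie.frame_interval,
                   pixel_size=movie.pixel_size, stim_frame=movie.stim_frame,
                   stim_site=movie.stim_site)
    base = Movie(frames=movie.frames, frame_interval=movie.frame_interval,
                 pixel_size=movie.pixel_size, stim_frame=movie.stim_frame,
                 stim_site=movie.stim_site)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c1, m1, _ = analyze_movie(base)
        c2, m2, _ = analyze_movie(scaled)
    assert list(c1.recruited) == list(c2.recruited)
    assert list(c1.ring_index) == list(c2.ring_index)
    assert m1.cells_per_ring == m2.cells_per_ring
    assert m1.max_length == pytest.approx(m2.max_length)
    assert m1.speed == pytest.approx(m2.speed, nan_ok=True)
    # raw-amplitude metrics scale linearly, dF/F metrics do not change
    assert m2.mean_amplitude == pytest.approx(3.7 * m1.mean_amplitude)
    assert np.allclose(c1.peak_dff, c2.peak_dff)


def test_prestimulus_dff_mean_is_zero(small_movie):
    """F_b is the pre-stimulus mean, so pre-stimulus dF/F averages to 0."""
    movie, tr = small_movie
    from calwave.wave import extract_traces
    rois = ROISet.from_centroids(tr[["x", "y"]].to_numpy(), movie.shape,
                                 radius_px=2.0)
    traces = extract_traces(movie, rois)
    for raw in traces:
        fb = raw[:movie.stim_frame].mean()
        dff = dff_trace(raw, fb)
        assert abs(dff[:movie.stim_frame].mean()) < 1e-12


class TestDetectRois:
    def test_blank_movie_yields_empty_set(self):
        m = _movie_from_frames(np.full((30, 32, 32), 100.0))
        assert len(detect_rois(m, expected_radius=5.0)) == 0

    def test_recall_on_planted_cells(self):
        cfg = SimulationConfig(seed=11)
        movie, truth = simulate_movie(cfg)
        rec = np.array([t.centroid for t in truth if t.recruited])
        rois = detect_rois(movie, expected_radius=cfg.cell_radius)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(rois.centroids).query(rec)
        r_px = cfg.cell_radius / cfg.pixel_size
        assert (d <= r_px).mean() >= 0.95

    def test_rois_are_disjoint_disks(self):
        rois = ROISet.from_centroids([(5.0, 5.0), (8.0, 5.0)], (16, 16), 3.0)
        assert rois.labels.max() == 2          # overlap resolved by nearest
        assert (rois.labels >= 0).all()

    def test_csv_injection_path(self, tmp_path):
        p = tmp_path / "rois.csv"
        pd.DataFrame({"id": [3, 9], "x": [4.0, 12.0], "y": [4.0, 12.0]}
                     ).to_csv(p, index=False)
        rois = ROISet.from_csv(p, (20, 20), radius_px=2.0)
        assert list(rois.ids) == [3, 9]
        assert len(rois) == 2
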