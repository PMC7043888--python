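"""Neural response statistics: windowed responses, responsiveness
classifiers, sparseness, tuning curves, ramp indices and regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import changedet as cd
from changedet.response_metrics import (OMISSION_RAMP, PRE_STIMULUS_RAMP,
                                        STIMULUS_RAMP)


def _mini_traces(matrix, frame_rate=30.0):
    n_cells, n_frames = matrix.shape
    return cd.EventTraces(
        frame_times=np.arange(n_frames) / frame_rate,
        matrix=np.asarray(matrix, dtype=float),
        cells=pd.DataFrame({"cell_id": np.arange(n_cells),
                            "cell_class": "excitatory", "mode": "",
                            "preferred_image": -1}),
        condition="novel", frame_rate=frame_rate)


def _mini_stimuli(n_flash, images=None, omitted=None):
    onsets = np.arange(n_flash) * 0.75
    return pd.DataFrame({
        "flash_index": np.arange(n_flash), "onset": onsets,
        "offset": onsets + 0.25,
        "image_id": images if images is not None else np.zeros(n_flash, int),
        "is_change": 0,
        "is_omitted": omitted if omitted is not None
        else np.zeros(n_flash, int),
        "trial_id": 0})


class TestFlashResponses:
    def test_zero_trace_zero_responses(self):
        traces = _mini_traces(np.zeros((2, 300)))
        out = cd.flash_responses(traces, _mini_stimuli(10))
        assert (out["response"] == 0.0).all()

    def test_event_outside_window_ignored(self):
        m = np.zeros((1, 300))
        m[0, 18] = 5.0  # 0.6 s after the t=0 flash: outside 500 ms window
        out = cd.flash_responses(_mini_traces(m), _mini_stimuli(8))
        first = out[out["flash_index"] == 0]["response"].iloc[0]
        assert first == 0.0

    def test_matches_frame_average_oracle(self, rng):
        m = rng.random((3, 400))
        stim = _mini_stimuli(12, omitted=np.r_[np.zeros(11, int), 1])
        traces = _mini_traces(m)
        out = cd.flash_responses(traces, stim)
        for row in out.itertuples():
            onset = stim.loc[stim["flash_index"] == row.flash_index,
                             "onset"].iloc[0]
            width = 0.75 if row.is_omitted else 0.50
            sel = (traces.frame_times >= onset) & \
                (traces.frame_times < onset + width)
            assert row.response == pytest.approx(m[row.cell_id, sel].mean())


class TestPreferredImage:
    def test_argmax_selected(self):
        m = np.zeros((1, 400))
        stim = _mini_stimuli(12, images=np.arange(12) % 3)
        m[0, np.flatnonzero(stim["image_id"].to_numpy() == 1) * 22] = 0.0
        # put events only on flashes of image 1
        for fi in stim[stim["image_id"] == 1]["flash_index"]:
            m[0, int(fi * 0.75 * 30) + 2] = 4.0
        out = cd.preferred_image(cd.flash_responses(_mini_traces(m), stim))
        assert out.iloc[0] == 1

    def test_all_zero_ties_to_lowest_image(self):
        stim = _mini_stimuli(12, images=np.arange(12) % 4)
        out = cd.preferred_image(
            cd.flash_responses(_mini_traces(np.zeros((1, 400))), stim))
        assert out.iloc[0] == 0

    def test_matches_bruteforce_argmax(self, rng):
        vals = rng.random((200, 8))
        rows = []
        for cid in range(200):
            for img in range(8):
                rows.append(dict(cell_id=cid, flash_index=img,
                                 image_id=img, is_change=0, is_omitted=0,
                                 response=vals[cid, img]))
        out = cd.preferred_image(pd.DataFrame(rows))
        assert np.array_equal(out.to_numpy(), vals.argmax(axis=1))


class TestResponsivenessClassifier:
    def test_all_zero_cell_not_responsive(self, rng):
        flag, p = cd.classify_responsiveness(
            np.zeros(20), np.zeros(50), presentation_frac=0.25, rng=rng)
        assert not flag
        assert np.allclose(p, 1.0)

    def test_clear_responders_flagged(self, rng):
        null = rng.random(100)
        target = np.r_[np.full(6, 2.0), np.zeros(14)]  # 30 % exceed null max
        flag, p = cd.classify_responsiveness(target, null,
                                             presentation_frac=0.25, rng=rng)
        assert flag
        assert (p[:6] == 0.0).all()

    def test_below_fraction_not_flagged(self, rng):
        null = rng.random(100)
        target = np.r_[np.full(4, 2.0), np.zeros(16)]  # only 20 %
        flag, _ = cd.classify_responsiveness(target, null,
                                             presentation_frac=0.25, rng=rng)
        assert not flag

    def test_empty_null_rejected(self, rng):
        with pytest.raises(ValueError):
            cd.classify_responsiveness(np.ones(5), np.empty(0), rng=rng)

    def test_null_calibration_small(self):
        # exchangeable targets/nulls: responsive rate well below 5 %
        rng = np.random.default_rng(99)
        n_resp = 0
        for _ in range(200):
            flag, _ = cd.classify_responsiveness(
                rng.random(50), rng.random(50), n_resamples=2000,
                presentation_frac=0.25, rng=rng)
            n_resp += flag
        assert n_resp / 200 < 0.05


class TestLifetimeSparseness:
    def test_one_hot_is_one(self):
        r = np.zeros(8)
        r[3] = 2.5
        assert cd.lifetime_sparseness(r) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert cd.lifetime_sparseness(np.full(8, 0.7)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_image_responder(self):
        r = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        assert cd.lifetime_sparseness(r) == pytest.approx(0.857, abs=0.001)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cd.lifetime_sparseness(np.zeros(8))

    @settings(max_examples=200, deadline=None)
    @given(hnp.arrays(float, 8,
                      elements=st.one_of(st.just(0.0),
                                         st.floats(1e-3, 100))))
    def test_bounded_in_unit_interval(self, r):
        if r.sum() == 0:
            return
        s = cd.lifetime_sparseness(r)
        assert -1e-9 <= s <= 1.0 + 1e-9


class TestPopulationTuningCurve:
    def test_single_cell_is_own_sorted_tuning(self, rng):
        vals = rng.random(8)
        rows = [dict(cell_id=0, flash_index=i, image_id=i, is_change=0,
                     is_omitted=0, response=vals[i]) for i in range(8)]
        curve = cd.population_tuning_curve(pd.DataFrame(rows), [0])
        assert np.allclose(curve, np.sort(vals)[::-1])

    def test_two_cells_positionwise_mean(self):
        a = np.array([3.0, 1.0, 2.0, 0, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 1.0, 5.0, 0, 0.5])
        rows = []
        for cid, v in ((0, a), (1, b)):
            rows += [dict(cell_id=cid, flash_index=i, image_id=i,
                          is_change=0, is_omitted=0, response=v[i])
                     for i in range(8)]
        curve = cd.population_tuning_curve(pd.DataFrame(rows), [0, 1])
        expected = (np.sort(a)[::-1] + np.sort(b)[::-1]) / 2
        assert np.allclose(curve, expected)

    def test_curve_is_non_increasing(self, rng):
        rows = []
        for cid in range(5):
            v = rng.random(8)
            rows += [dict(cell_id=cid, flash_index=i, image_id=i,
                          is_change=0, is_omitted=0, response=v[i])
                     for i in range(8)]
        curve = cd.population_tuning_curve(pd.DataFrame(rows), range(5))
        assert np.all(np.diff(curve) <= 1e-12)


class TestTriggeredAverageAndPeak:
    def test_planted_peak_recovered(self):
        fr = 30.0
        ft = np.arange(0, 60, 1 / fr)
        trace = np.zeros_like(ft)
        anchors = np.arange(5, 50, 0.75 * 8)
        for a in anchors:
            trace[int(round((a + 0.1) * fr))] = 1.0  # peak 100 ms post
        _, _, ttp = cd.mean_trace_and_peak(ft, trace, anchors,
                                           frame_rate=fr)
        assert ttp == pytest.approx(0.1, abs=1 / fr)

    def test_peak_search_restricted_to_window(self):
        fr = 30.0
        ft = np.arange(0, 30, 1 / fr)
        trace = np.zeros_like(ft)
        anchor = [10.0]
        trace[int(10.2 * fr)] = 1.0     # local max inside window
        trace[int(10.6 * fr)] = 5.0     # global max outside 500 ms
        _, _, ttp = cd.mean_trace_and_peak(ft, trace, anchor, frame_rate=fr)
        assert ttp == pytest.approx(0.2, abs=1 / fr)

    def test_argmax_matches_bruteforce(self, rng):
        fr = 30.0
        ft = np.arange(0, 40, 1 / fr)
        trace = rng.random(ft.size)
        anchors = rng.uniform(2, 38, 20)
        t_rel, mean, ttp = cd.mean_trace_and_peak(ft, trace, anchors,
                                                  frame_rate=fr)
        sel = (t_rel >= 0) & (t_rel <= 0.5)
        assert ttp == t_rel[sel][np.argmax(mean[sel])]


class TestRampIndex:
    t_rel = np.arange(-23, 24) / 30.0

    def test_flat_trace_zero(self):
        trace = np.full_like(self.t_rel, 2.0)
        assert cd.ramp_index(trace, self.t_rel, PRE_STIMULUS_RAMP) == \
            pytest.approx(0.0, abs=1e-6)

    def test_increasing_prestimulus_trace_positive(self):
        trace = np.linspace(0.1, 2.0, self.t_rel.size)
        assert cd.ramp_index(trace, self.t_rel, PRE_STIMULUS_RAMP) > 0

    def test_doubling_trace_gives_one(self):
        trace = np.full_like(self.t_rel, 1.0)
        # last 4 frames of the 400 ms window (120 ms at 30 Hz)
        late = (self.t_rel >= -4 / 30.0 - 1e-9) & (self.t_rel < -1e-9)
        trace[late] = 2.0
        ri = cd.ramp_index(trace, self.t_rel, PRE_STIMULUS_RAMP)
        assert ri == pytest.approx(1.0, abs=0.01)

    def test_antisymmetric_under_time_reversal(self, rng):
        # reverse the trace within the symmetric omission window
        t = np.arange(0, 23) / 30.0
        trace = rng.random(23) + 0.5
        fwd = cd.ramp_index(trace, t, OMISSION_RAMP)
        rev = cd.ramp_index(trace[::-1], t, OMISSION_RAMP)
        assert fwd == pytest.approx(-rev, abs=1e-6)

    def test_matches_direct_formula(self, rng):
        trace = rng.random(self.t_rel.size) + 0.1
        ri = cd.ramp_index(trace, self.t_rel, STIMULUS_RAMP)
        sel = (self.t_rel >= -1e-9) & (self.t_rel < 0.125 - 1e-9)
        seg = trace[sel]
        expected = np.log2((seg[-2:].mean() + 1e-6) /
                           (seg[:2].mean() + 1e-6))
        assert ri == pytest.approx(expected)

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            cd.ramp_index(np.ones(3), np.arange(3) / 30.0,
                          PRE_STIMULUS_RAMP)


class TestIndexCorrelation:
    def test_identity_perfectly_correlated(self, rng):
        x = rng.random(50)
        r, p, slope, _ = cd.index_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_negation_anticorrelated(self, rng):
        x = rng.random(50)
        r, _, _, _ = cd.index_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        x, y = rng.random(200), rng.random(200)
        r, _, _, _ = cd.index_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() *
                                             (yc ** 2).sum())
        assert r == pytest.approx(expected)

    def test_zero_variance_flagged_nan(self):
        r, *_ = cd.index_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r)


class TestPopulationDirectionality:
    def test_familiar_vip_majority_suppressed_and_omission_responsive(
            self, familiar_vip_cells):
        _, cells = familiar_vip_cells
        assert (cells["dynamics_class"] == "stimulus_suppressed").mean() > 0.5
        assert cells["omission_responsive"].mean() > 0.5

    def test_novel_vip_majority_driven(self, novel_vip_cells):
        _, cells = novel_vip_cells
        assert (cells["dynamics_class"] == "stimulus_driven").mean() > 0.5
        assert cells["stimulus_ramp_index"].median() > 0

    def test_familiar_vip_prestimulus_ramp_positive(self,
                                                    familiar_vip_cells):
        traces, cells = familiar_vip_cells
        ramping = traces.cells[traces.cells["mode"] == "vip_ramping"]
        sub = cells[cells["cell_id"].isin(ramping["cell_id"])]
        assert sub["pre_stimulus_ramp_index"].median() > 0

    def test_mixed_vip_indices_negatively_correlated(
            self, familiar_vip_cells, novel_vip_cells):
        _, fam = familiar_vip_cells
        _, nov = novel_vip_cells
        both = pd.concat([fam, nov])
        r, _, _, _ = cd.index_correlation(
            both["pre_stimulus_ramp_index"], both["stimulus_ramp_index"])
        assert r < 0
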