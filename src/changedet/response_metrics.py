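"""Neural response statistics on calcium event traces.

All analysis operates on detected events (non-negative magnitudes, a.u.).
Per-presentation responses are means over a 500 ms window after stimulus
onset (covering the 250 ms flash plus 250 ms for delayed/off responses)
or a 750 ms window after a scheduled-but-omitted flash.  On top of these:

* preferred image — the image evoking the largest mean response;
* responsiveness — resampling classifiers: each presentation of the
  preferred image is assigned a p-value against 10,000 resamples of the
  cell's omission responses (and each omission against resampled image
  responses); a cell is image-responsive if >= 25 % of preferred-image
  presentations have p < 0.05, omission-responsive at the 10 % fraction;
* lifetime sparseness — tuning-curve concentration in [0, 1];
* ramp indices — log2 of late-window over early-window mean activity,
  positive when the trace rises across the window; computed over the
  pre-stimulus window (400 ms before onset, first vs last 120 ms), the
  stimulus window (125 ms from onset, first vs last 65 ms) and the
  omission window (750 ms, split in half).  The sign of the stimulus
  ramp index classifies cells as stimulus-driven vs stimulus-suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity_synthesizer import EventTraces
from .signal_processing import SmoothingParams, smooth_events

logger = logging.getLogger("changedet")

STIMULUS_DRIVEN = "stimulus_driven"
STIMULUS_SUPPRESSED = "stimulus_suppressed"


@dataclass
class ResponseWindowSpec:
    """Response windows: 500 ms after stimulus onset, 750 ms after the
    scheduled onset of an omitted flash."""

    stimulus_window: float = 0.500
    omission_window: float = 0.750


@dataclass
class RampWindowSpec:
    """A ramp-index window relative to an anchor event.

    ``window`` is (start, end) seconds relative to the anchor; the early
    and late sub-windows are the first ``early_len`` and last
    ``late_len`` seconds of it (they may overlap when the sub-windows
    exceed half the window, as the 65+65 ms stimulus spec does within
    125 ms).
    """

    window: tuple[float, float]
    early_len: float
    late_len: float


# anchor = stimulus onset
PRE_STIMULUS_RAMP = RampWindowSpec(window=(-0.400, 0.0),
                                   early_len=0.120, late_len=0.120)
STIMULUS_RAMP = RampWindowSpec(window=(0.0, 0.125),
                               early_len=0.065, late_len=0.065)
# alternative anchoring at stimulus offset (250 ms after onset)
STIMULUS_RAMP_FROM_OFFSET = RampWindowSpec(window=(0.250, 0.375),
                                           early_len=0.065, late_len=0.065)
# anchor = scheduled onset of the omitted flash
OMISSION_RAMP = RampWindowSpec(window=(0.0, 0.750),
                               early_len=0.375, late_len=0.375)


# ---------------------------------------------------------------------------
# windowed responses
# ---------------------------------------------------------------------------

def flash_responses(traces: EventTraces, stimuli: pd.DataFrame,
                    spec: ResponseWindowSpec = ResponseWindowSpec()
                    ) -> pd.DataFrame:
    """Per cell x presentation mean response matrix (long format).

    Each presented flash contributes the mean event magnitude over
    frames in [onset, onset + 500 ms); omitted slots use the 750 ms
    window anchored at the scheduled (never shown) onset.  Presentations
    whose window runs past the end of the trace are dropped.
    """
    onsets = stimuli["onset"].to_numpy(dtype=float)
    omitted = stimuli["is_omitted"].to_numpy(dtype=bool)
    widths = np.where(omitted, spec.omission_window, spec.stimulus_window)
    ft = traces.frame_times
    i0 = np.searchsorted(ft, onsets, side="left")
    i1 = np.searchsorted(ft, onsets + widths, side="left")
    keep = (i1 <= len(ft)) & (i1 > i0) & (onsets + widths <= ft[-1] + 1e-9)
    if not keep.all():
        logger.info("flash_responses: dropped %d presentations whose "
                    "window exceeds the trace", int((~keep).sum()))
    # mean over window via cumulative sums: all cells at once
    csum = np.concatenate(
        [np.zeros((traces.matrix.shape[0], 1)),
         np.cumsum(traces.matrix, axis=1)], axis=1)
    sums = csum[:, i1[keep]] - csum[:, i0[keep]]
    means = sums / (i1[keep] - i0[keep])

    n_cells = traces.matrix.shape[0]
    kept = stimuli.loc[keep, ["flash_index", "image_id", "is_change",
                              "is_omitted"]].reset_index(drop=True)
    frames = []
    for cid in range(n_cells):
        df = kept.copy()
        df.insert(0, "cell_id", cid)
        df["response"] = means[cid]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def preferred_image(matrix: pd.DataFrame) -> pd.Series:
    """Image evoking the largest mean response, per cell.

    Computed over presented (non-omitted) flashes; ties break to the
    lowest image index.
    """
    pres = matrix[matrix["is_omitted"] == 0]
    means = pres.groupby(["cell_id", "image_id"])["response"].mean().unstack()
    # idxmax breaks ties at the first (lowest) column label
    return means.idxmax(axis=1).astype(int).rename("preferred_image")


# ---------------------------------------------------------------------------
# responsiveness resampling classifier
# ---------------------------------------------------------------------------

def classify_responsiveness(target_responses: Sequence[float],
                            null_responses: Sequence[float],
                            n_resamples: int = 10_000,
                            presentation_frac: float = 0.25,
                            alpha: float = 0.05,
                            rng: Optional[np.random.Generator] = None
                            ) -> tuple[bool, np.ndarray]:
    """Resampling test of per-presentation responses against a null pool.

    The null pool is resampled with replacement ``n_resamples`` times;
    each target presentation gets p = proportion of resampled null
    values >= that response (ties count against significance, so an
    all-zero cell is never responsive).  The cell is flagged responsive
    when the fraction of presentations with p < alpha reaches
    ``presentation_frac`` (0.25 for image-responsiveness against
    omission nulls, 0.10 for omission-responsiveness against image
    nulls).
    """
    target = np.asarray(target_responses, dtype=float)
    null = np.asarray(null_responses, dtype=float)
    if null.size == 0:
        raise ValueError("empty null response pool")
    if target.size == 0:
        return False, np.empty(0)
    if rng is None:
        rng = np.random.default_rng(0)
    draws = np.sort(rng.choice(null, size=n_resamples, replace=True))
    n_ge = n_resamples - np.searchsorted(draws, target, side="left")
    p = n_ge / n_resamples
    flag = bool(np.mean(p < alpha) >= presentation_frac)
    return flag, p


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def lifetime_sparseness(tuning: Sequence[float]) -> float:
    """Lifetime sparseness S in [0, 1] of a non-negative tuning vector.

    S = (1 - (sum(r)/N)^2 / (sum(r^2)/N)) / (1 - 1/N): 1 for a cell
    responding to a single image, 0 for uniform tuning.
    """
    r = np.asarray(tuning, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("sparseness needs at least two images")
    if np.any(r < 0):
        raise ValueError("tuning responses must be non-negative")
    denom = np.sum(r ** 2) / n
    if denom == 0:
        raise ValueError("sparseness undefined for an all-zero tuning")
    return float((1.0 - (np.sum(r) / n) ** 2 / denom) / (1.0 - 1.0 / n))


def population_tuning_curve(matrix: pd.DataFrame,
                            responsive_cells: Sequence[int]) -> np.ndarray:
    """Rank-sorted mean tuning curve averaged across responsive cells.

    Each cell's per-image mean responses are sorted descending, then
    averaged position-wise; the result is non-increasing by construction.
    """
    cells = list(responsive_cells)
    if not cells:
        raise ValueError("population tuning curve needs >= 1 cell")
    pres = matrix[(matrix["is_omitted"] == 0) &
                  matrix["cell_id"].isin(cells)]
    means = pres.groupby(["cell_id", "image_id"])["response"].mean().unstack()
    ranked = np.sort(means.to_numpy(), axis=1)[:, ::-1]
    return ranked.mean(axis=0)


# ---------------------------------------------------------------------------
# triggered averages, time-to-peak, ramp indices
# ---------------------------------------------------------------------------

def event_triggered_average(frame_times: np.ndarray, trace: np.ndarray,
                            anchors: Sequence[float],
                            window: tuple[float, float] = (-0.75, 0.75),
                            frame_rate: float = 30.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean trace around anchor events on a relative frame grid."""
    frame_times = np.asarray(frame_times, dtype=float)
    trace2d = np.atleast_2d(np.asarray(trace, dtype=float))
    k0 = int(np.floor(window[0] * frame_rate))
    k1 = int(np.ceil(window[1] * frame_rate))
    offsets = np.arange(k0, k1 + 1)
    t_rel = offsets / frame_rate
    base = np.searchsorted(frame_times, np.asarray(anchors, float),
                           side="left")
    idx = base[:, None] + offsets[None, :]
    ok = (idx[:, 0] >= 0) & (idx[:, -1] < len(frame_times))
    if not ok.any():
        raise ValueError("no anchor has full window coverage")
    mean = trace2d[:, idx[ok]].mean(axis=1)
    return t_rel, (mean[0] if np.asarray(trace).ndim == 1 else mean)


def time_to_peak(t_rel: np.ndarray, mean_trace: np.ndarray,
                 window: float = 0.500) -> float:
    """Time of the maximum of the triggered average within [0, window]."""
    sel = (t_rel >= 0) & (t_rel <= window + 1e-9)
    if not sel.any():
        raise ValueError("trace does not cover the peak window")
    seg = np.asarray(mean_trace)[sel]
    return float(t_rel[sel][int(np.argmax(seg))])


def mean_trace_and_peak(frame_times: np.ndarray, trace: np.ndarray,
                        anchors: Sequence[float], window: float = 0.500,
                        frame_rate: float = 30.0
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Stimulus-triggered average and its time to peak.

    Returns ``(t_rel, mean_trace, time_to_peak)`` where the average runs
    over [-0.75, +0.75] s around the anchors and the peak is searched in
    [0, window].
    """
    t_rel, mean = event_triggered_average(frame_times, trace, anchors,
                                          frame_rate=frame_rate)
    return t_rel, mean, time_to_peak(t_rel, mean, window)


def ramp_index(mean_trace: np.ndarray, t_rel: np.ndarray,
               spec: RampWindowSpec, frame_rate: float = 30.0,
               eps: float = 1e-6) -> float:
    """log2 ratio of late-window to early-window mean activity.

    R_early is the mean over the first ``early_len`` seconds of the
    window and R_late over the last ``late_len``; the index is
    log2((R_late + eps) / (R_early + eps)), positive when the trace is
    increasing across the window and negative when it is decreasing.
    Sub-window lengths are rounded to the nearest whole frame; window
    membership is half-open [start, end).
    """
    t_rel = np.asarray(t_rel, dtype=float)
    mean_trace = np.asarray(mean_trace, dtype=float)
    sel = (t_rel >= spec.window[0] - 1e-9) & (t_rel < spec.window[1] - 1e-9)
    seg = mean_trace[sel]
    k_early = max(int(round(spec.early_len * frame_rate)), 1)
    k_late = max(int(round(spec.late_len * frame_rate)), 1)
    if seg.size < max(k_early, k_late):
        raise ValueError(
            f"trace covers {seg.size} frames of window {spec.window}, "
            f"need {max(k_early, k_late)}")
    r_early = float(seg[:k_early].mean())
    r_late = float(seg[-k_late:].mean())
    return float(np.log2((r_late + eps) / (r_early + eps)))


def index_correlation(x: Sequence[float], y: Sequence[float]
                      ) -> tuple[float, float, float, float]:
    """Least-squares regression between two per-cell indices.

    Returns ``(r, p, slope, intercept)``; raises on fewer than three
    finite pairs, returns NaN r (flagged via warning) on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least three finite pairs")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("index_correlation: zero variance, r undefined")
        return np.nan, np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    return (float(res.rvalue), float(res.pvalue), float(res.slope),
            float(res.intercept))


# ---------------------------------------------------------------------------
# per-cell summary
# ---------------------------------------------------------------------------

def summarize_cells(traces: EventTraces, stimuli: pd.DataFrame,
                    spec: ResponseWindowSpec = ResponseWindowSpec(),
                    stimulus_ramp_spec: RampWindowSpec = STIMULUS_RAMP,
                    n_resamples: int = 10_000,
                    smooth: bool = True,
                    seed: int = 0) -> pd.DataFrame:
    """Full per-cell analysis: one summary row per cell.

    Event traces are causally smoothed first (matching the processing
    chain); windowed responses, preferred image, the two resampling
    responsiveness classifiers, lifetime sparseness (image-responsive
    cells only), time to peak, the three ramp indices, and the
    stimulus-driven/suppressed dynamics class.
    """
    rng = np.random.default_rng(seed)
    if smooth:
        sm = SmoothingParams()
        work = EventTraces(
            frame_times=traces.frame_times,
            matrix=np.vstack([smooth_events(row, sm, traces.frame_rate)
                              for row in traces.matrix]),
            cells=traces.cells, condition=traces.condition,
            frame_rate=traces.frame_rate, ground_truth=traces.ground_truth)
    else:
        work = traces

    matrix = flash_responses(work, stimuli, spec)
    pref = preferred_image(matrix)
    presented = stimuli[(stimuli["is_omitted"] == 0)]
    omissions = stimuli[stimuli["is_omitted"] == 1]
    stim_anchors = presented["onset"].to_numpy()
    om_anchors = omissions["onset"].to_numpy()

    rows = []
    for cid in range(work.matrix.shape[0]):
        cell = matrix[matrix["cell_id"] == cid]
        pres = cell[cell["is_omitted"] == 0]
        om = cell[cell["is_omitted"] == 1]["response"].to_numpy()
        p_img = int(pref.loc[cid])
        target = pres[pres["image_id"] == p_img]["response"].to_numpy()

        img_resp = om_resp = None
        if om.size:
            img_resp, _ = classify_responsiveness(
                target, om, n_resamples=n_resamples,
                presentation_frac=0.25, rng=rng)
            om_resp, _ = classify_responsiveness(
                om, pres["response"].to_numpy(), n_resamples=n_resamples,
                presentation_frac=0.10, rng=rng)

        tuning = pres.groupby("image_id")["response"].mean() \
            .reindex(range(int(stimuli["image_id"].max()) + 1), fill_value=0.0)
        sparse = np.nan
        if img_resp and tuning.to_numpy().sum() > 0:
            sparse = lifetime_sparseness(tuning.to_numpy())

        t_rel, mean_tr, ttp = mean_trace_and_peak(
            work.frame_times, work.matrix[cid], stim_anchors,
            frame_rate=work.frame_rate)
        pre_ri = ramp_index(mean_tr, t_rel, PRE_STIMULUS_RAMP,
                            work.frame_rate)
        stim_ri = ramp_index(mean_tr, t_rel, stimulus_ramp_spec,
                             work.frame_rate)
        om_ri = np.nan
        if om_anchors.size:
            t_om, mean_om = event_triggered_average(
                work.frame_times, work.matrix[cid], om_anchors,
                window=(0.0, 0.78), frame_rate=work.frame_rate)
            om_ri = ramp_index(mean_om, t_om, OMISSION_RAMP, work.frame_rate)

        rows.append(dict(
            cell_id=cid,
            cell_class=work.cells.loc[cid, "cell_class"],
            mode=work.cells.loc[cid, "mode"],
            condition=work.condition,
            preferred_image=p_img,
            image_responsive=img_resp,
            omission_responsive=om_resp,
            sparseness=sparse,
            time_to_peak=ttp,
            pre_stimulus_ramp_index=pre_ri,
            stimulus_ramp_index=stim_ri,
            omission_ramp_index=om_ri,
            dynamics_class=STIMULUS_DRIVEN if stim_ri > 0
            else STIMULUS_SUPPRESSED,
        ))
    return pd.DataFrame(rows)
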