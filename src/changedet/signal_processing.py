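"""Trace-level processing: neuropil subtraction, rolling-mode dF/F,
causal event smoothing, clock alignment, and pupillometry cleanup.

These are the deterministic transforms that sit between raw fluorescence
(or tracked pupil points) and the response metrics.  The fluorescence
model is FM = FC + r*FN: the measured somatic trace is contaminated by a
fraction ``r`` of the surrounding neuropil signal, and the true trace is
recovered by subtraction.  dF/F uses a trailing 180 s rolling-mode
baseline; event traces are smoothed with a causal half-Gaussian
(SD 65 ms) so no activity is attributed to times before it occurred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("changedet")


@dataclass
class DffParams:
    """Rolling-mode baseline parameters.

    ``baseline_window`` is the trailing window (seconds) over which the
    modal fluorescence value is taken as F0; ``mode_bin_width`` is the
    histogram bin used to estimate the mode of a continuous-valued trace
    (default 0.1 % of the trace range).
    """

    baseline_window: float = 180.0
    mode_bin_width: Optional[float] = None


@dataclass
class SmoothingParams:
    """Causal half-Gaussian filter: SD 0.065 s, truncated at 4 SD,
    unit-sum normalized (total event mass is conserved)."""

    sd: float = 0.065
    support_sd: float = 4.0


def subtract_neuropil(FM: np.ndarray, FN: np.ndarray, r: float) -> np.ndarray:
    """Recover the true somatic trace FC = FM - r*FN."""
    FM = np.asarray(FM, dtype=float)
    FN = np.asarray(FN, dtype=float)
    if FM.shape != FN.shape:
        raise ValueError(
            f"trace length mismatch: {FM.shape} vs {FN.shape}")
    if r < 0:
        raise ValueError("contamination ratio r must be >= 0")
    return FM - r * FN


def compute_dff(F: np.ndarray, frame_rate: float,
                params: DffParams = DffParams()) -> np.ndarray:
    """dF/F with a trailing rolling-mode baseline.

    F0 at each frame is the histogram mode (bin width
    ``mode_bin_width``, default 0.1 % of the trace range) of F over the
    trailing ``baseline_window`` seconds, clipped at the trace start so
    the baseline never peeks forward.  Ties go to the lowest bin.
    """
    F = np.asarray(F, dtype=float)
    n = len(F)
    win = max(int(round(params.baseline_window * frame_rate)), 1)
    lo, hi = float(F.min()), float(F.max())
    if hi == lo:
        F0 = np.full(n, lo)
    else:
        bw = params.mode_bin_width or 1e-3 * (hi - lo)
        bins = np.minimum(((F - lo) / bw).astype(np.int64),
                          int((hi - lo) / bw))
        counts = np.zeros(bins.max() + 1, dtype=np.int64)
        F0 = np.empty(n)
        for i in range(n):
            counts[bins[i]] += 1
            if i >= win:
                counts[bins[i - win]] -= 1
            F0[i] = lo + (int(counts.argmax()) + 0.5) * bw
    bad = F0 <= 0
    if bad.any():
        raise ValueError(
            f"nonpositive baseline F0 at frame {int(np.argmax(bad))}")
    return (F - F0) / F0


def half_gaussian_kernel(params: SmoothingParams,
                         frame_rate: float) -> np.ndarray:
    """Causal half-Gaussian weights (lag >= 0 only), unit sum."""
    n = int(np.ceil(params.support_sd * params.sd * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    w = np.exp(-t ** 2 / (2.0 * params.sd ** 2))
    return w / w.sum()


def smooth_events(events: np.ndarray,
                  params: SmoothingParams = SmoothingParams(),
                  frame_rate: float = 30.0) -> np.ndarray:
    """Causal half-Gaussian smoothing of an event trace.

    The output at frame t depends only on events at frames <= t; total
    mass is conserved (the kernel sums to 1, edge losses excepted).
    """
    events = np.asarray(events, dtype=float)
    kernel = half_gaussian_kernel(params, frame_rate)
    return np.convolve(events, kernel)[: len(events)]


def align_frames(frame_times: np.ndarray,
                 stimulus_times: np.ndarray) -> np.ndarray:
    """Map each imaging frame to the latest stimulus clock time strictly
    before it.

    Returns an integer index into ``stimulus_times`` per frame, with -1
    for frames that precede every stimulus time.  The strictly-before
    rule guarantees responses are never attributed to stimuli occurring
    after the frame was acquired; a frame exactly coincident with a
    stimulus time maps to the *previous* one.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    stimulus_times = np.asarray(stimulus_times, dtype=float)
    for name, arr in (("frame_times", frame_times),
                      ("stimulus_times", stimulus_times)):
        if np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} must be sorted ascending")
    return np.searchsorted(stimulus_times, frame_times, side="left") - 1


# ---------------------------------------------------------------------------
# pupillometry
# ---------------------------------------------------------------------------

MIN_CONFIDENCE = 0.8
MIN_POINTS = 6


def fit_pupil_ellipse(points: np.ndarray, confidences: np.ndarray
                      ) -> Optional[dict]:
    """Least-squares ellipse fit to high-confidence tracked points.

    Uses only points with confidence >= 0.8; returns None (missing) when
    fewer than six such points remain or the geometry is degenerate.
    The returned dict carries center, semi-axes (major >= minor),
    orientation, and ``area`` = area of a circle whose radius is the
    major *semi*-axis (the full-axis reading would quadruple it; the
    semi-axis convention is used throughout).
    """
    from skimage.measure import EllipseModel

    points = np.asarray(points, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    good = points[confidences >= MIN_CONFIDENCE]
    if len(good) < MIN_POINTS:
        return None
    with np.errstate(all="ignore"):
        model = EllipseModel.from_estimate(good)
    if not model:
        return None
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        return None
    major, minor = (a, b) if a >= b else (b, a)
    if minor / major < 1e-3:
        return None  # near-collinear points: degenerate fit
    return dict(center=(float(xc), float(yc)), semi_major=float(major),
                semi_minor=float(minor), orientation=float(theta),
                area=float(np.pi * major ** 2))


def clean_pupil_trace(area: np.ndarray, n_sd: float = 3.0,
                      pad_frames: int = 2) -> np.ndarray:
    """Clean a pupil-area trace: outlier removal and interpolation.

    Frames more than ``n_sd`` standard deviations from the trace mean
    are excluded, as are the ``pad_frames`` frames immediately before and
    after each run of missing fits; everything excluded or missing is
    linearly interpolated (flat extrapolation at the edges).
    """
    area = np.asarray(area, dtype=float)
    missing = ~np.isfinite(area)
    if missing.all():
        raise ValueError("pupil trace has no valid frames")
    valid = area[~missing]
    mu, sd = valid.mean(), valid.std()
    drop = missing.copy()
    if sd > 0:
        drop |= np.abs(area - mu) > n_sd * sd
    # pad around runs of *missing* fits (blinks)
    pad = missing.copy()
    for k in range(1, pad_frames + 1):
        pad[:-k] |= missing[k:]
        pad[k:] |= missing[:-k]
    drop |= pad
    if drop.all():
        raise ValueError("no frames survive pupil-trace cleaning")
    s = pd.Series(np.where(drop, np.nan, area))
    return s.interpolate(method="linear", limit_direction="both").to_numpy()
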