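"""Behavioral performance measures for change-detection sessions.

Hit and false-alarm rates are fractions of engaged go/catch trials with a
lick inside the 750 ms response window; sensitivity is the signal-
detection d' = Z[hit] - Z[fa] with Z the inverse normal CDF.  Engagement
is defined as epochs where the subject earns at least two rewards per
minute (centered rolling window).  Flash-wise response rates extend the
trial rates to individual presentations, omissions, and the flash
directly after an omission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .task_simulator import CATCH, GO, TaskParams

RUNNING = "running"
STATIONARY = "stationary"


@dataclass
class EngagementMask:
    """Boolean engagement trace on a uniform time grid."""

    times: np.ndarray
    engaged: np.ndarray
    window: float
    threshold: float

    def at(self, t) -> np.ndarray:
        """Engagement state at arbitrary times (nearest grid point)."""
        idx = np.clip(np.searchsorted(self.times, np.atleast_1d(t)),
                      0, len(self.times) - 1)
        return self.engaged[idx]


@dataclass
class BehaviorMetrics:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    n_engaged_go_trials: int
    n_engaged_catch_trials: int
    flash_response_rate: float = np.nan
    omission_response_rate: float = np.nan
    post_omission_response_rate: float = np.nan


def compute_engagement_mask(reward_times: Sequence[float], duration: float,
                            window: float = 300.0, threshold: float = 2.0,
                            dt: float = 1.0) -> EngagementMask:
    """Engagement = rolling reward rate >= ``threshold`` rewards/minute.

    The window is centered and clipped at the session edges; the rate is
    computed over the actual window overlap, and the threshold is
    inclusive (exactly 2/min counts as engaged).
    """
    rewards = np.sort(np.asarray(reward_times, dtype=float))
    times = np.arange(0.0, duration + dt / 2, dt)
    lo = np.clip(times - window / 2.0, 0.0, duration)
    hi = np.clip(times + window / 2.0, 0.0, duration)
    counts = np.searchsorted(rewards, hi, side="right") - \
        np.searchsorted(rewards, lo, side="left")
    minutes = np.maximum(hi - lo, dt) / 60.0
    rate = counts / minutes
    return EngagementMask(times=times, engaged=rate >= threshold,
                          window=window, threshold=threshold)


def response_rates(trials: pd.DataFrame, mask: Optional[EngagementMask],
                   stimuli: Optional[pd.DataFrame] = None,
                   lick_times: Optional[np.ndarray] = None,
                   response_window: float = 0.750) -> BehaviorMetrics:
    """Hit/false-alarm rates over engaged trials, plus flash-wise rates.

    Free-reward and aborted trials are excluded.  When a stimulus table
    and lick stream are supplied, per-flash response rates are computed
    for non-change presented flashes, omission slots, and the flash
    immediately following an omission.  Rates with no qualifying trials
    are NaN.
    """
    done = trials[trials["outcome"].isin(
        ["HIT", "MISS", "FALSE_ALARM", "CORRECT_REJECTION"])]
    if mask is not None:
        engaged = mask.at(done["change_onset"].to_numpy())
        done = done[engaged]
    go = done[done["trial_type"] == GO]
    catch = done[done["trial_type"] == CATCH]
    hit_rate = float((go["outcome"] == "HIT").mean()) if len(go) else np.nan
    fa_rate = float((catch["outcome"] == "FALSE_ALARM").mean()) \
        if len(catch) else np.nan
    dp = dprime(hit_rate, fa_rate, len(go), len(catch)) \
        if len(go) and len(catch) else np.nan

    flash_rr = omission_rr = post_om_rr = np.nan
    if stimuli is not None and lick_times is not None:
        licks = np.sort(np.asarray(lick_times, dtype=float))

        def _rate(onsets: np.ndarray) -> float:
            if len(onsets) == 0:
                return np.nan
            nxt = np.searchsorted(licks, onsets, side="right")
            has = (nxt < len(licks)) & \
                (licks[np.clip(nxt, 0, len(licks) - 1)] <=
                 onsets + response_window)
            return float(has.mean())

        omitted = stimuli["is_omitted"].to_numpy(dtype=bool)
        change = stimuli["is_change"].to_numpy(dtype=bool)
        post_om = np.zeros_like(omitted)
        post_om[1:] = omitted[:-1]
        onsets = stimuli["onset"].to_numpy()
        flash_rr = _rate(onsets[~omitted & ~change])
        omission_rr = _rate(onsets[omitted])
        post_om_rr = _rate(onsets[post_om & ~omitted])

    return BehaviorMetrics(
        hit_rate=hit_rate, false_alarm_rate=fa_rate, d_prime=dp,
        n_engaged_go_trials=len(go), n_engaged_catch_trials=len(catch),
        flash_response_rate=flash_rr, omission_response_rate=omission_rr,
        post_omission_response_rate=post_om_rr)


def dprime(hit_rate: float, false_alarm_rate: float,
           n_go: int, n_catch: int) -> float:
    """d' = Z[hit] - Z[fa] with rates clipped away from 0 and 1.

    Rates are clipped to [1/(2n), 1 - 1/(2n)] of their respective trial
    counts so that perfect or empty rates stay finite.
    """
    if n_go <= 0 or n_catch <= 0:
        raise ValueError("d' undefined without go and catch trials")
    h = float(np.clip(hit_rate, 0.5 / n_go, 1.0 - 0.5 / n_go))
    f = float(np.clip(false_alarm_rate, 0.5 / n_catch, 1.0 - 0.5 / n_catch))
    return float(norm.ppf(h) - norm.ppf(f))


def reaction_times(trials: pd.DataFrame,
                   lick_times: Sequence[float]) -> pd.Series:
    """Latency of the first lick after the change on each go trial.

    NaN when no lick follows the change.  Latencies are not truncated at
    the response window (the HIT/MISS decision is, but the reported
    latency is the raw first-lick time).
    """
    licks = np.sort(np.asarray(lick_times, dtype=float))
    go = trials[trials["trial_type"] == GO]
    out = {}
    for row in go.itertuples():
        change = float(row.change_onset)
        if not np.isfinite(change):
            out[row.trial_id] = np.nan
            continue
        i = np.searchsorted(licks, change, side="right")
        out[row.trial_id] = float(licks[i] - change) if i < len(licks) \
            else np.nan
    return pd.Series(out, name="reaction_time")


def classify_locomotor_state(speed_times: np.ndarray, speed: np.ndarray,
                             event_times: Sequence[float],
                             window: tuple[float, float] = (-0.5, 0.75),
                             threshold: float = 5.0) -> list[Optional[str]]:
    """Label each event running/stationary by mean speed in a window.

    The flash window is [-0.5, +0.75] s around stimulus onset; omission
    contexts use +/-2 s.  Running requires strictly greater than the
    5 cm/s threshold; events whose window falls outside the trace get
    None.
    """
    speed_times = np.asarray(speed_times, dtype=float)
    speed = np.asarray(speed, dtype=float)
    labels: list[Optional[str]] = []
    for t in np.atleast_1d(event_times):
        lo, hi = t + window[0], t + window[1]
        if lo < speed_times[0] - 1e-9 or hi > speed_times[-1] + 1e-9:
            labels.append(None)
            continue
        i0 = np.searchsorted(speed_times, lo, side="left")
        i1 = np.searchsorted(speed_times, hi, side="right")
        if i1 <= i0:
            labels.append(None)
            continue
        labels.append(RUNNING if speed[i0:i1].mean() > threshold
                      else STATIONARY)
    return labels
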