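"""Synthetic calcium event traces with planted response structure.

Generates per-cell event-magnitude time series (30 Hz imaging clock) whose
statistics mirror the phenomenology the analysis stages are built to
detect:

* excitatory cells — image-tuned transient responses locked to stimulus
  onset; under the familiar condition amplitudes shrink and tuning
  sharpens;
* VIP cells, "driven" mode (novel images) — untuned stimulus-locked
  responses;
* VIP cells, "suppressed-ramping" mode (familiar images) — activity ramps
  up through the inter-stimulus interval, peaks at stimulus onset, is
  suppressed by the stimulus, and keeps ramping through omitted flashes
  until the next presented stimulus.

Events are an inhomogeneous Poisson process on the frame grid with
exponential magnitude marks; the planted ground truth (mode, preferred
image, rate profile) is retained for recovery tests.  A forward
fluorescence model (exponential calcium kernel plus neuropil
contamination, FM = FC + r*FN) supports end-to-end tests of the trace
processing stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

CONTINUE_RAMP = "continue_ramp"
SILENT = "silent"


@dataclass
class PopulationParams:
    """Composition and statistics of one synthetic population.

    Default counts match typical per-session yields (~180 excitatory,
    ~15 VIP cells).  ``vip_mode_fractions`` defaults per condition:
    familiar populations are mostly suppressed-ramping, novel populations
    mostly driven.
    """

    n_excitatory: int = 180
    n_vip: int = 15
    condition: str = "novel"          # "familiar" | "novel"
    frame_rate: float = 30.0
    tuning_sharpness: float = 1.0     # 1/decay constant of tuning weights
    exc_amplitude_scale: float = 1.0
    familiar_amplitude_factor: float = 0.65
    familiar_sharpness_factor: float = 1.5
    vip_mode_fractions: Optional[dict] = None
    noise_event_rate: float = 0.05    # background events/s
    event_magnitude_mean: float = 1.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_excitatory < 0 or self.n_vip < 0:
            raise ValueError("cell counts must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.condition not in ("familiar", "novel"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.vip_mode_fractions is not None:
            tot = sum(self.vip_mode_fractions.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("vip_mode_fractions must sum to 1")

    def mode_fractions(self) -> dict:
        if self.vip_mode_fractions is not None:
            return dict(self.vip_mode_fractions)
        if self.condition == "familiar":
            return {"driven": 0.2, "suppressed_ramping": 0.8}
        return {"driven": 0.8, "suppressed_ramping": 0.2}


@dataclass
class RateProfile:
    """Event-rate model for one cell over the 750 ms flash cycle.

    ``rate(t_in_cycle, image_id, t_since_presented)`` gives the
    instantaneous rate in events/s.  ``omission_rule`` says what the cell
    does during an omitted flash: ``continue_ramp`` keeps integrating time
    since the last *presented* stimulus (the ramp keeps growing through
    the gap); ``silent`` falls back to baseline.
    """

    kind: str                       # "exc" | "vip_driven" | "vip_ramping"
    omission_rule: str
    peak_rate: float
    baseline: float
    preferred_image: Optional[int] = None
    tuning_weights: Optional[np.ndarray] = None
    bump_center: float = 0.13
    bump_sd: float = 0.05
    ramp_onset: float = 0.15        # suppression dead-time before ramping
    ramp_cap: float = 2.0           # rate cap (multiples of peak) in gaps

    def rate(self, t_in_cycle: np.ndarray, image_id: np.ndarray,
             t_since_presented: np.ndarray, period: float = 0.75
             ) -> np.ndarray:
        t = np.asarray(t_in_cycle, dtype=float)
        out = np.full(t.shape, self.baseline, dtype=float)
        if self.kind in ("exc", "vip_driven"):
            bump = np.exp(-0.5 * ((t - self.bump_center) / self.bump_sd) ** 2)
            if self.kind == "exc":
                w = self.tuning_weights[np.asarray(image_id, dtype=int)]
            else:
                w = 1.0
            out = out + self.peak_rate * w * bump
        elif self.kind == "vip_ramping":
            # ramp in time since the last *presented* flash: restarts at a
            # presentation, keeps growing through omissions (expectation
            # signal), capped at ramp_cap * peak_rate
            ts = np.asarray(t_since_presented, dtype=float)
            frac = (ts - self.ramp_onset) / (period - self.ramp_onset)
            frac = np.clip(frac, 0.0, self.ramp_cap)
            out = out + self.peak_rate * frac
        else:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        return np.clip(out, 0.0, None)


def make_rate_profile(cell_class: str, condition: str,
                      params: PopulationParams, rng: np.random.Generator,
                      mode: Optional[str] = None) -> RateProfile:
    """Draw one cell's rate profile.

    ``mode`` selects the VIP profile explicitly; when omitted it is drawn
    from the population's mode fractions.
    """
    params.validate()
    if cell_class == "excitatory":
        amp = 25.0 * params.exc_amplitude_scale
        sharp = params.tuning_sharpness
        if condition == "familiar":
            amp *= params.familiar_amplitude_factor
            sharp *= params.familiar_sharpness_factor
        pref = int(rng.integers(8))
        idx = np.arange(8)
        dist = np.minimum(np.abs(idx - pref), 8 - np.abs(idx - pref))
        weights = np.exp(-dist * sharp)
        return RateProfile(kind="exc", omission_rule=SILENT, peak_rate=amp,
                           baseline=0.0, preferred_image=pref,
                           tuning_weights=weights)
    if cell_class == "vip":
        if mode is None:
            fr = params.mode_fractions()
            mode = "driven" if rng.random() < fr.get("driven", 0.0) \
                else "suppressed_ramping"
        if mode == "driven":
            return RateProfile(kind="vip_driven", omission_rule=SILENT,
                               peak_rate=20.0, baseline=1.0,
                               bump_center=0.15, bump_sd=0.06)
        return RateProfile(kind="vip_ramping", omission_rule=CONTINUE_RAMP,
                           peak_rate=20.0, baseline=0.5)
    raise ValueError(f"unknown cell class {cell_class!r}")


@dataclass
class EventTraces:
    """Population event traces on a common imaging clock.

    ``matrix`` is cells x frames, non-negative event magnitudes (a.u.).
    ``cells`` holds one row per cell (cell_id, cell_class, mode,
    preferred_image); ``ground_truth`` maps cell_id to its generating
    :class:`RateProfile`.
    """

    frame_times: np.ndarray
    matrix: np.ndarray
    cells: pd.DataFrame
    condition: str
    frame_rate: float
    ground_truth: dict = field(default_factory=dict)

    def trace(self, cell_id: int) -> np.ndarray:
        return self.matrix[int(cell_id)]

    def to_long_frame(self) -> pd.DataFrame:
        n_cells, n_frames = self.matrix.shape
        return pd.DataFrame({
            "cell_id": np.repeat(np.arange(n_cells), n_frames),
            "frame_time": np.tile(self.frame_times, n_cells),
            "magnitude": self.matrix.ravel(),
        })


def _frame_context(stimuli: pd.DataFrame, frame_times: np.ndarray,
                   period: float) -> tuple[np.ndarray, ...]:
    """Per-frame slot context: time-in-cycle, image, omitted flag and time
    since the last presented flash."""
    onsets = stimuli["onset"].to_numpy()
    omitted = stimuli["is_omitted"].to_numpy(dtype=bool)
    images = stimuli["image_id"].to_numpy()
    slot = np.searchsorted(onsets, frame_times, side="right") - 1
    slot = np.clip(slot, 0, len(onsets) - 1)
    t_in_cycle = frame_times - onsets[slot]
    presented = onsets[~omitted]
    if presented.size == 0:
        raise ValueError("stimulus table contains no presented flashes")
    pidx = np.searchsorted(presented, frame_times, side="right") - 1
    t_since_presented = np.where(pidx >= 0,
                                 frame_times - presented[np.clip(pidx, 0, None)],
                                 t_in_cycle)
    return t_in_cycle, images[slot], omitted[slot], t_since_presented


def generate_event_traces(stimuli: pd.DataFrame, pop: PopulationParams,
                          seed: int) -> EventTraces:
    """Sample a population of event traces driven by a stimulus table.

    Each cell's per-frame event count is Poisson with mean rate*dt from
    its rate profile (omitted slots follow the profile's omission rule);
    event magnitudes are exponential marks, so a frame with k events
    carries a Gamma(k) magnitude.  Background events occur everywhere at
    ``noise_event_rate``.
    """
    if seed is None:
        raise ValueError("generate_event_traces requires an explicit seed")
    pop.validate()
    rng = np.random.default_rng(seed)
    period = float(np.median(np.diff(stimuli["onset"].to_numpy())))
    t_end = float(stimuli["onset"].iloc[-1]) + period
    dt = 1.0 / pop.frame_rate
    frame_times = np.arange(0.0, t_end, dt)
    t_cyc, img, omit, t_pres = _frame_context(stimuli, frame_times, period)

    classes = (["excitatory"] * pop.n_excitatory) + (["vip"] * pop.n_vip)
    # fixed per-population mode counts (not per-cell draws) so small
    # populations still realize the configured mixture
    fr = pop.mode_fractions()
    n_driven = int(round(fr.get("driven", 0.0) * pop.n_vip))
    vip_modes = ["driven"] * n_driven + \
                ["suppressed_ramping"] * (pop.n_vip - n_driven)

    rows, profiles = [], {}
    matrix = np.zeros((len(classes), len(frame_times)))
    vip_i = 0
    for cid, cls in enumerate(classes):
        if cls == "vip":
            profile = make_rate_profile(cls, pop.condition, pop, rng,
                                        mode=vip_modes[vip_i])
            vip_i += 1
        else:
            profile = make_rate_profile(cls, pop.condition, pop, rng)
        rate = profile.rate(t_cyc, img, t_pres, period)
        if profile.omission_rule == SILENT:
            rate = np.where(omit, profile.baseline, rate)
        rate = rate + pop.noise_event_rate
        counts = rng.poisson(rate * dt)
        mags = np.zeros_like(rate)
        nz = counts > 0
        if nz.any():
            mags[nz] = rng.gamma(shape=counts[nz],
                                 scale=pop.event_magnitude_mean)
        matrix[cid] = mags
        mode = profile.kind if cls == "vip" else ""
        rows.append(dict(cell_id=cid, cell_class=cls, mode=mode,
                         preferred_image=profile.preferred_image
                         if profile.preferred_image is not None else -1))
        profiles[cid] = profile

    cells = pd.DataFrame(rows)
    return EventTraces(frame_times=frame_times, matrix=matrix, cells=cells,
                       condition=pop.condition, frame_rate=pop.frame_rate,
                       ground_truth=profiles)


# ---------------------------------------------------------------------------
# fluorescence forward model
# ---------------------------------------------------------------------------

@dataclass
class FluorescencePair:
    """Forward-modeled fluorescence for one cell: FM = FC_true + r*FN."""

    FM: np.ndarray
    FN: np.ndarray
    FC_true: np.ndarray
    r: float
    F0_true: float
    kernel_tau: float
    frame_rate: float


def render_fluorescence(events: np.ndarray, frame_rate: float,
                        kernel_tau: float = 0.7, r: float = 0.7,
                        F0: float = 100.0, noise_sd: float = 0.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> FluorescencePair:
    """Render an event trace into a measured/neuropil fluorescence pair.

    FC_true = F0 + events convolved with a causal exponential kernel
    (decay ``kernel_tau``); FN is an independent smooth positive trace;
    FM is composed exactly as FC_true + r*FN plus optional white
    measurement noise.
    """
    events = np.asarray(events, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(events)
    t = np.arange(n) / frame_rate
    kernel = np.exp(-np.arange(n) / (kernel_tau * frame_rate))
    fc = F0 + np.convolve(events, kernel)[:n]
    white = rng.normal(0.0, 1.0, size=n)
    win = max(int(frame_rate), 1)
    smooth = np.convolve(white, np.ones(win) / win, mode="same")
    fn = 0.3 * F0 * (1.0 + 0.1 * smooth)
    fm = fc + r * fn
    if noise_sd > 0:
        fm = fm + rng.normal(0.0, noise_sd, size=n)
    return FluorescencePair(FM=fm, FN=fn, FC_true=fc, r=r, F0_true=F0,
                            kernel_tau=kernel_tau, frame_rate=frame_rate)


def write_event_traces(out_dir, traces: EventTraces) -> None:
    """Write traces as long-format CSV plus a JSON ground-truth sidecar."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces.to_long_frame().to_csv(out / "event_traces.csv", index=False)
    truth = {
        str(cid): dict(kind=p.kind, omission_rule=p.omission_rule,
                       peak_rate=p.peak_rate, baseline=p.baseline,
                       preferred_image=p.preferred_image)
        for cid, p in traces.ground_truth.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    traces.cells.to_csv(out / "cells.csv", index=False)
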