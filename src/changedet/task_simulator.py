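"""Generative model of the visual change-detection task.

A session is a continuous 60-min series of image flashes on a fixed 750 ms
period (250 ms image + 500 ms gray).  Go/catch trials are interleaved on top
of the flash grid: on a go trial the image identity changes at a scheduled
change time drawn from a truncated exponential (2.25-8.25 s, mean 4.25 s);
on a catch trial nothing changes at the sham change time.  The simulated
agent (standing in for the mouse) licks stochastically; licks before the
(sham) change abort and restart the trial, licks inside the 750 ms response
window after a change score a HIT (go) or FALSE ALARM (catch).

Image identity follows a pre-generated "transition path": an Eulerian
circuit through the complete directed graph on the image set including
self-loops, so every ordered image pair - including same-to-same, which
defines a catch trial - occurs exactly once per path.  With 8 images this
yields 64 transitions of which 8 are self-pairs, i.e. a 12.5 % catch rate.

Five percent of flashes are omitted at random (gray screen continues),
excluding the change flash and the flash immediately before it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger("changedet")

# Trial outcome labels
HIT = "HIT"
MISS = "MISS"
FALSE_ALARM = "FALSE_ALARM"
CORRECT_REJECTION = "CORRECT_REJECTION"
ABORTED = "ABORTED"

GO = "go"
CATCH = "catch"
FREE_REWARD = "free_reward"


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class TaskParams:
    """Structural parameters of the change-detection task.

    Defaults reproduce the imaging-phase configuration: 1-hour sessions,
    250/500 ms flash/gray, change times 2.25-8.25 s with mean 4.25 s,
    12.5 % catch frequency (structural: 1/8 of transitions are self-pairs),
    5 % flash omission, 8 natural images.
    """

    session_duration: float = 3600.0
    flash_duration: float = 0.250
    gray_duration: float = 0.500
    response_window: float = 0.750
    change_time_min: float = 2.25
    change_time_max: float = 8.25
    change_time_mean: float = 4.25
    catch_fraction: float = 0.125
    omission_probability: float = 0.05
    n_images: int = 8
    n_transition_paths: int = 1000
    max_trial_repeats: int = 5
    n_initial_free_rewards: int = 5
    miss_streak_for_free_reward: int = 10
    stimulus_clock_rate: float = 60.0

    @property
    def flash_period(self) -> float:
        return self.flash_duration + self.gray_duration

    def validate(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if not (self.change_time_min < self.change_time_mean < self.change_time_max):
            raise ValueError(
                "change_time_mean must lie strictly between change_time_min "
                "and change_time_max"
            )
        for name in ("catch_fraction", "omission_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.flash_period <= 0:
            raise ValueError("flash period must be positive")


@dataclass
class AgentParams:
    """Stochastic licking/locomotion model of the simulated subject.

    ``p_hit`` is the per-go-trial probability of a rewarded lick in the
    response window; ``p_spontaneous_lick_per_flash`` drives pre-change
    licks, which abort trials.  Reaction times are truncated normal on
    (0, response_window].
    """

    p_hit: float = 0.80
    p_false_alarm_per_catch: float = 0.25
    p_spontaneous_lick_per_flash: float = 0.02
    reaction_time_mean: float = 0.35
    reaction_time_sd: float = 0.10
    run_fraction: float = 0.5
    run_speed_mean: float = 10.0
    pupil_baseline: float = 1000.0
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("p_hit", "p_false_alarm_per_catch",
                     "p_spontaneous_lick_per_flash", "run_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


NEVER_LICK = AgentParams(p_hit=0.0, p_false_alarm_per_catch=0.0,
                         p_spontaneous_lick_per_flash=0.0)
ALWAYS_ABORT = AgentParams(p_hit=0.0, p_false_alarm_per_catch=0.0,
                           p_spontaneous_lick_per_flash=1.0)


@dataclass
class BehaviorStreams:
    """Continuous behavioral read-outs for one session.

    Running speed is sampled on the 60 Hz stimulus clock, pupil area at
    30 Hz; lick and reward times are event lists in seconds.
    """

    lick_times: np.ndarray
    reward_times: np.ndarray
    running_speed: pd.DataFrame    # columns: time, speed (cm/s), 60 Hz
    pupil_area: pd.DataFrame       # columns: time, area (a.u.), 30 Hz


# ---------------------------------------------------------------------------
# change-time sampler
# ---------------------------------------------------------------------------

def _truncated_exp_mean(scale: float, upper: float) -> float:
    # E[X | X <= upper] for X ~ Exp(scale)
    z = math.exp(-upper / scale)
    return scale - upper * z / (1.0 - z)


@lru_cache(maxsize=32)
def _calibrated_scale(span: float, target_mean: float) -> float:
    """Exponential scale whose truncation at ``span`` has mean ``target_mean``.

    The truncated mean is monotone in the scale, so a bracketed root-find
    suffices.  For the default task (span 6.0 s, target 2.0 s) the solution
    is ~2.80 s.
    """
    if not 0.0 < target_mean < span / 2.0:
        # mean of Exp truncated at span is in (0, span/2)
        raise ValueError(
            f"target truncated mean {target_mean} infeasible for span {span}"
        )
    return brentq(lambda s: _truncated_exp_mean(s, span) - target_mean,
                  1e-6, 1e6, xtol=1e-12)


def change_time_scale(params: TaskParams) -> float:
    """Calibrated exponential scale of the change-time distribution."""
    span = params.change_time_max - params.change_time_min
    mean = params.change_time_mean - params.change_time_min
    return _calibrated_scale(span, mean)


def sample_change_time(params: TaskParams, rng: np.random.Generator) -> float:
    """Draw one scheduled change time (seconds from trial start).

    Offset + exponential, rejection-resampled above the upper bound, with
    the scale calibrated so the truncated mean equals ``change_time_mean``.
    Catch sham times use this identical sampler.
    """
    return float(sample_change_times(params, rng, 1)[0])


def sample_change_times(params: TaskParams, rng: np.random.Generator,
                        n: int) -> np.ndarray:
    """Vectorized draw of ``n`` change times."""
    params.validate()
    span = params.change_time_max - params.change_time_min
    scale = change_time_scale(params)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.exponential(scale, size=max(n - filled, 16))
        draws = draws[draws <= span]
        take = min(len(draws), n - filled)
        out[filled:filled + take] = draws[:take]
        filled += take
    return params.change_time_min + out


# ---------------------------------------------------------------------------
# transition paths
# ---------------------------------------------------------------------------

def generate_transition_path(n_images: int,
                             rng: np.random.Generator) -> list[int]:
    """One Eulerian circuit through the complete digraph with self-loops.

    Randomized Hierholzer traversal: every node has equal in/out degree
    ``n_images`` and the graph is strongly connected, so a circuit using
    each of the ``n_images**2`` ordered transitions exactly once always
    exists.  Returned path has length ``n_images**2 + 1``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    adj = {i: list(rng.permutation(n_images)) for i in range(n_images)}
    stack = [int(rng.integers(n_images))]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(int(adj[v].pop()))
        else:
            circuit.append(stack.pop())
    return circuit[::-1]


def generate_transition_paths(n_paths: int, n_images: int,
                              rng: np.random.Generator) -> list[list[int]]:
    """Matrix of pre-generated transition paths (one list per path)."""
    return [generate_transition_path(n_images, rng) for _ in range(n_paths)]


def _rotate_path_to(path: Sequence[int], start: int) -> list[int]:
    # Eulerian circuits are cyclic: rotate so the path begins at `start`.
    body = list(path[:-1])  # drop duplicated endpoint
    if start not in body:
        return list(path)
    k = body.index(start)
    rotated = body[k:] + body[:k]
    rotated.append(rotated[0])
    return rotated


# ---------------------------------------------------------------------------
# trial scoring
# ---------------------------------------------------------------------------

def score_trial(trial_type: str, trial_start: float, change_time: float,
                lick_times: Sequence[float], params: TaskParams) -> str:
    """Score one trial attempt from its lick times.

    Any lick in [trial_start, change_time] aborts.  A go trial with a lick
    in (change, change + response_window] is a HIT, else a MISS; a catch
    trial with a lick in the sham window is a FALSE ALARM, else a CORRECT
    REJECTION.  The window is half-open on the left and closed on the
    right, so a lick at exactly +750 ms still counts.
    """
    licks = np.asarray(lick_times, dtype=float)
    if licks.size and np.any((licks >= trial_start) & (licks <= change_time)):
        return ABORTED
    in_window = licks.size and np.any(
        (licks > change_time) & (licks <= change_time + params.response_window)
    )
    if trial_type == CATCH:
        return FALSE_ALARM if in_window else CORRECT_REJECTION
    return HIT if in_window else MISS


# ---------------------------------------------------------------------------
# omission scheduling
# ---------------------------------------------------------------------------

def schedule_omissions(table: pd.DataFrame, p: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Flag eligible flashes as omitted with independent probability ``p``.

    Eligible = not a change flash and not the flash immediately preceding
    a change flash.  Omitted flashes keep their slot: the gray screen
    simply continues through the scheduled presentation.
    """
    table = table.copy()
    is_change = table["is_change"].to_numpy(dtype=bool)
    pre_change = np.zeros_like(is_change)
    pre_change[:-1] = is_change[1:]
    eligible = ~is_change & ~pre_change
    draws = rng.random(len(table))
    table["is_omitted"] = (eligible & (draws < p)).astype(int)
    return table


# ---------------------------------------------------------------------------
# agent behavior helpers
# ---------------------------------------------------------------------------

def _draw_reaction_time(agent: AgentParams, task: TaskParams,
                        rng: np.random.Generator) -> float:
    # truncated normal on (0, response_window]
    for _ in range(1000):
        rt = rng.normal(agent.reaction_time_mean, agent.reaction_time_sd)
        if 0.0 < rt <= task.response_window:
            return float(rt)
    return min(max(agent.reaction_time_mean, 1e-3), task.response_window)


def _running_trace(duration: float, agent: AgentParams,
                   rng: np.random.Generator,
                   rate: float = 60.0) -> pd.DataFrame:
    """Bouted running-speed trace at the stimulus clock rate.

    Alternating bouts (exponential durations, mean 10 s) are labelled
    running with probability ``run_fraction``; speed within a running bout
    fluctuates around ``run_speed_mean`` and is clipped at zero.
    """
    t = np.arange(0.0, duration, 1.0 / rate)
    speed = np.zeros_like(t)
    pos = 0.0
    while pos < duration:
        bout = float(rng.exponential(10.0))
        running = rng.random() < agent.run_fraction
        i0 = int(pos * rate)
        i1 = min(int((pos + bout) * rate), len(t))
        if running and i1 > i0:
            speed[i0:i1] = agent.run_speed_mean + \
                rng.normal(0.0, 0.2 * agent.run_speed_mean, size=i1 - i0)
        pos += bout
    # slow smoothing keeps bout structure but removes frame-to-frame jumps
    kernel = np.ones(9) / 9.0
    speed = np.convolve(speed, kernel, mode="same")
    return pd.DataFrame({"time": t, "speed": np.clip(speed, 0.0, None)})


def _pupil_trace(duration: float, agent: AgentParams,
                 rng: np.random.Generator,
                 rate: float = 30.0) -> pd.DataFrame:
    """Pupil-area trace: baseline plus slow drift, 30 Hz."""
    t = np.arange(0.0, duration, 1.0 / rate)
    drift = np.cumsum(rng.normal(0.0, 1.0, size=len(t)))
    if len(t) > 1:
        drift -= np.linspace(drift[0], drift[-1], len(t))
    area = agent.pupil_baseline * (1.0 + 0.05 * drift / max(np.abs(drift).max(), 1.0))
    return pd.DataFrame({"time": t, "area": area})


def generate_agent_behavior(trials: pd.DataFrame, task: TaskParams,
                            agent: AgentParams,
                            rng: np.random.Generator) -> BehaviorStreams:
    """Sample behavior streams for an already-scheduled trial table.

    Emits hit licks with probability ``p_hit`` at change + reaction time,
    false-alarm licks on catch trials, spontaneous per-flash licks, plus
    running-speed and pupil-area traces.  Used standalone for agent-model
    tests; :func:`simulate_session` interleaves the same draws with trial
    scheduling so that spontaneous licks can abort and restart trials.
    """
    agent.validate()
    licks: list[float] = []
    rewards: list[float] = []
    period = task.flash_period
    for row in trials.itertuples():
        start, change = float(row.trial_start), float(row.change_onset)
        n_pre = max(int((change - start) / period), 0)
        for k in range(n_pre):
            if rng.random() < agent.p_spontaneous_lick_per_flash:
                licks.append(start + k * period + float(rng.uniform(0, period)))
        if row.trial_type == CATCH:
            if rng.random() < agent.p_false_alarm_per_catch:
                licks.append(change + _draw_reaction_time(agent, task, rng))
        else:
            if row.trial_type == FREE_REWARD:
                rewards.append(change)
            if rng.random() < agent.p_hit:
                lick = change + _draw_reaction_time(agent, task, rng)
                licks.append(lick)
                if row.trial_type == GO:
                    rewards.append(lick)
    duration = float(task.session_duration)
    return BehaviorStreams(
        lick_times=np.sort(np.asarray(licks)),
        reward_times=np.sort(np.asarray(rewards)),
        running_speed=_running_trace(duration, agent, rng,
                                     task.stimulus_clock_rate),
        pupil_area=_pupil_trace(duration, agent, rng),
    )


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def simulate_session(task: TaskParams, agent: AgentParams, seed: int
                     ) -> tuple[pd.DataFrame, pd.DataFrame, BehaviorStreams]:
    """Simulate one full behavior session.

    Returns ``(stimulus_table, trial_table, behavior_streams)``.  Sessions
    open with ``n_initial_free_rewards`` free-reward trials; an extra free
    reward is issued once ``miss_streak_for_free_reward`` consecutive MISS
    outcomes accumulate since the last reward.  Aborted trials repeat the
    same scheduled change time up to ``max_trial_repeats`` times, after
    which the trial is recorded ABORTED and the session moves on.

    The trial sequence advances one transition per trial along a randomly
    selected pre-generated transition path (self-transition = catch trial);
    exhausted paths are replaced by a fresh random path rotated to start at
    the current image, preserving image continuity.
    """
    if seed is None:
        raise ValueError("simulate_session requires an explicit seed")
    task.validate()
    agent.validate()
    rng = np.random.default_rng(seed)
    period = task.flash_period
    n_slots = int(math.floor(task.session_duration / period))
    onsets = np.arange(n_slots) * period

    paths = generate_transition_paths(task.n_transition_paths, task.n_images,
                                      rng)
    path = list(paths[int(rng.integers(len(paths)))])
    pos = 0  # index into path; transition = (path[pos], path[pos+1])

    slot_image = np.full(n_slots, -1, dtype=int)
    slot_trial = np.full(n_slots, -1, dtype=int)
    slot_change = np.zeros(n_slots, dtype=bool)

    trials: list[dict] = []
    licks: list[float] = []
    rewards: list[float] = []
    cursor = 0
    current_image = path[0]
    miss_streak = 0
    trial_id = 0
    resp_slots = int(math.ceil(task.response_window / period))

    while True:
        # draw a fresh path (rotated onto the current image, circuits are
        # cyclic) when the previous one is exhausted, or when an ABORTED
        # trial skipped its transition and desynchronized the path from
        # the image actually on screen
        if pos >= len(path) - 1 or path[pos] != current_image:
            path = _rotate_path_to(
                paths[int(rng.integers(len(paths)))], current_image)
            pos = 0
        src, dst = path[pos], path[pos + 1]
        is_free = (trial_id < task.n_initial_free_rewards or
                   miss_streak >= task.miss_streak_for_free_reward)
        if is_free:
            trial_type = FREE_REWARD
        else:
            trial_type = CATCH if src == dst else GO
        sct = sample_change_time(task, rng)
        d_slots = int(math.ceil(sct / period - 1e-9))

        n_repeats = 0
        outcome = None
        trial_start_slot = cursor
        trial_licks: list[float] = []
        trial_rewards: list[float] = []
        change_onset = np.nan
        while True:
            attempt_slot = cursor
            change_slot = attempt_slot + d_slots
            if change_slot + resp_slots >= n_slots:
                outcome = "incomplete"
                break
            # pre-change flashes: spontaneous licks abort
            abort_slot = -1
            for k in range(attempt_slot, change_slot):
                if rng.random() < agent.p_spontaneous_lick_per_flash:
                    abort_slot = k
                    break
            slot_end = abort_slot + 1 if abort_slot >= 0 else change_slot + 1
            slot_image[attempt_slot:slot_end] = src
            slot_trial[attempt_slot:slot_end] = trial_id
            if abort_slot >= 0:
                lick = onsets[abort_slot] + float(rng.uniform(0, period))
                trial_licks.append(lick)
                cursor = abort_slot + 1
                if n_repeats >= task.max_trial_repeats:
                    outcome = ABORTED
                    break
                n_repeats += 1
                continue
            # completed attempt
            change_onset = float(onsets[change_slot])
            if trial_type != CATCH and dst != src:
                slot_image[change_slot] = dst
                slot_change[change_slot] = True
            if trial_type == FREE_REWARD:
                trial_rewards.append(change_onset)
            licked = False
            if trial_type == CATCH:
                if rng.random() < agent.p_false_alarm_per_catch:
                    trial_licks.append(
                        change_onset + _draw_reaction_time(agent, task, rng))
                    licked = True
                outcome = FALSE_ALARM if licked else CORRECT_REJECTION
            else:
                if rng.random() < agent.p_hit:
                    lick = change_onset + _draw_reaction_time(agent, task, rng)
                    trial_licks.append(lick)
                    licked = True
                    if trial_type == GO:
                        trial_rewards.append(lick)
                outcome = HIT if licked else MISS
            cursor = change_slot + 1
            current_image = dst
            break

        if outcome == "incomplete":
            break
        licks.extend(trial_licks)
        rewards.extend(trial_rewards)
        if trial_rewards:
            miss_streak = 0
        elif outcome == MISS and trial_type == GO:
            miss_streak += 1
        trials.append(dict(
            trial_id=trial_id, trial_type=trial_type,
            scheduled_change_time=sct,
            trial_start=float(onsets[trial_start_slot]),
            change_onset=change_onset, outcome=outcome,
            n_repeats=n_repeats,
            reward_times=";".join(f"{r:.4f}" for r in trial_rewards),
            n_rewards=len(trial_rewards),
        ))
        pos += 1
        trial_id += 1
        if outcome == ABORTED:
            current_image = src  # change never shown
        if cursor >= n_slots:
            break

    # tail flashes after the last trial keep showing the current image
    untouched = slot_image < 0
    slot_image[untouched] = current_image

    stim = pd.DataFrame({
        "flash_index": np.arange(n_slots),
        "onset": onsets,
        "offset": onsets + task.flash_duration,
        "image_id": slot_image,
        "is_change": slot_change.astype(int),
        "is_omitted": 0,
        "trial_id": slot_trial,
    })
    stim = schedule_omissions(stim, task.omission_probability, rng)
    trial_table = pd.DataFrame(trials)

    streams = BehaviorStreams(
        lick_times=np.sort(np.asarray(licks)),
        reward_times=np.sort(np.asarray(rewards)),
        running_speed=_running_trace(task.session_duration, agent, rng,
                                     task.stimulus_clock_rate),
        pupil_area=_pupil_trace(task.session_duration, agent, rng),
    )
    logger.info("simulated session: seed=%s trials=%d flashes=%d",
                seed, len(trial_table), n_slots)
    return stim, trial_table, streams


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_session(out_dir, stim: pd.DataFrame, trials: pd.DataFrame,
                  streams: BehaviorStreams) -> None:
    """Write session tables and behavior streams as CSV."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stim.to_csv(out / "stimulus_table.csv", index=False)
    trials.to_csv(out / "trial_table.csv", index=False)
    pd.DataFrame({"time": streams.lick_times}).to_csv(
        out / "licks.csv", index=False)
    pd.DataFrame({"time": streams.reward_times}).to_csv(
        out / "rewards.csv", index=False)
    streams.running_speed.to_csv(out / "running_speed.csv", index=False)
    streams.pupil_area.to_csv(out / "pupil_area.csv", index=False)
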