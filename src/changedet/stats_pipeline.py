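"""Group-level statistics and end-to-end pipeline orchestration.

Cross-condition comparisons follow the study's scheme: a one-way ANOVA
for an overall image-set effect, then Welch's (unequal-variance) t-test
for every image-set pair with Bonferroni-corrected significance
(alpha = 0.05 / number of pairs; 0.0083 for four image sets).
Confidence intervals are percentile-bootstrap intervals of the mean.

``run_pipeline`` chains the full synthetic study: simulate a behavior
session per condition (familiar image set A; novel sets B, C, D),
synthesize population event traces, compute behavioral metrics and
per-cell summaries, and compare metrics across image sets.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior_metrics as bm
from . import task_simulator as ts
from .activity_synthesizer import PopulationParams, generate_event_traces, \
    write_event_traces
from .response_metrics import summarize_cells
from .task_simulator import AgentParams, TaskParams, simulate_session, \
    write_session

logger = logging.getLogger("changedet")


@dataclass
class PairResult:
    group_a: str
    group_b: str
    welch_t: float
    welch_p: float
    significant: bool
    degenerate: bool = False


@dataclass
class ComparisonResult:
    metric: str
    anova_F: float
    anova_p: float
    corrected_alpha: float
    pairs: list[PairResult]


def compare_image_sets(groups: dict[str, Sequence[float]],
                       metric: str = "", alpha: float = 0.05
                       ) -> ComparisonResult:
    """ANOVA across image-set groups plus pairwise Welch t-tests.

    Significance of each pair is judged at the Bonferroni-corrected
    level alpha / n_pairs (0.05/6 = 0.0083 for four sets).  Pairwise
    tests are always computed regardless of the ANOVA outcome.
    """
    clean = {k: np.asarray(v, dtype=float)[np.isfinite(v)]
             for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    for k, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    with np.errstate(all="ignore"):
        F, p = stats.f_oneway(*clean.values())
    names = list(clean)
    pairs_idx = list(itertools.combinations(names, 2))
    corrected = alpha / len(pairs_idx)
    pairs = []
    for a, b in pairs_idx:
        degenerate = bool(clean[a].std() == 0 and clean[b].std() == 0)
        with np.errstate(all="ignore"):
            t, pp = stats.ttest_ind(clean[a], clean[b], equal_var=False)
        sig = bool(np.isfinite(pp) and pp < corrected)
        pairs.append(PairResult(a, b, float(t), float(pp), sig, degenerate))
    return ComparisonResult(metric=metric, anova_F=float(F),
                            anova_p=float(p), corrected_alpha=corrected,
                            pairs=pairs)


def bootstrap_ci(values: Sequence[float], level: float = 0.95,
                 n_boot: int = 1000,
                 rng: Optional[np.random.Generator] = None
                 ) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of the mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two values")
    if rng is None:
        rng = np.random.default_rng(0)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)),
            float(np.quantile(means, 1.0 - lo)))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_CONDITIONS = [("A", "familiar"), ("B", "novel"),
                      ("C", "novel"), ("D", "novel")]


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    task: TaskParams = field(default_factory=TaskParams)
    agent: AgentParams = field(default_factory=AgentParams)
    population: PopulationParams = field(default_factory=PopulationParams)
    conditions: list = field(default_factory=lambda:
                             [list(c) for c in DEFAULT_CONDITIONS])
    seed: int = 0
    bootstrap_seed: int = 1
    n_boot: int = 1000
    min_responsive_cells: int = 10

    def validate(self) -> None:
        self.task.validate()
        self.agent.validate()
        self.population.validate()
        if not self.conditions:
            raise ValueError("at least one condition is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            task=TaskParams(**raw.get("task", {})),
            agent=AgentParams(**raw.get("agent", {})),
            population=PopulationParams(**raw.get("population", {})),
        )
        for key in ("conditions", "seed", "bootstrap_seed", "n_boot",
                    "min_responsive_cells"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_yaml(self, path) -> None:
        doc = dict(task=asdict(self.task), agent=asdict(self.agent),
                   population=asdict(self.population),
                   conditions=self.conditions, seed=self.seed,
                   bootstrap_seed=self.bootstrap_seed, n_boot=self.n_boot,
                   min_responsive_cells=self.min_responsive_cells)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute simulate -> synthesize -> analyze -> compare and write a
    report bundle (CSV tables, JSON summary, plain-text log).

    Each condition gets its own derived seeds; identical configs and
    seeds reproduce byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"changedet pipeline seed={config.seed}"]
    summaries = {}
    behavior_rows = []
    for i, (name, condition) in enumerate(config.conditions):
        cond_seed = int(config.seed) * 1000 + i
        cond_dir = out / f"imageset_{name}"
        try:
            stim, trials, streams = simulate_session(
                config.task, config.agent, seed=cond_seed)
            write_session(cond_dir, stim, trials, streams)

            pop = PopulationParams(
                **{**asdict(config.population), "condition": condition})
            traces = generate_event_traces(stim, pop, seed=cond_seed + 1)
            write_event_traces(cond_dir, traces)

            mask = bm.compute_engagement_mask(
                streams.reward_times, config.task.session_duration)
            metrics = bm.response_rates(trials, mask, stimuli=stim,
                                        lick_times=streams.lick_times)
            behavior_rows.append(dict(image_set=name, condition=condition,
                                      **asdict(metrics)))

            cells = summarize_cells(traces, stim, seed=cond_seed + 2)
            cells.insert(0, "image_set", name)
            cells.to_csv(cond_dir / "cell_summary.csv", index=False)
            summaries[name] = cells
            log_lines.append(
                f"condition {name} ({condition}): seed={cond_seed} "
                f"trials={len(trials)} cells={len(cells)}")
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for image set {name}: {exc}"
            ) from exc

    behavior = pd.DataFrame(behavior_rows)
    behavior.to_csv(out / "behavior_metrics.csv", index=False)
    all_cells = pd.concat(summaries.values(), ignore_index=True)
    all_cells.to_csv(out / "cell_summary.csv", index=False)

    report = {"seed": config.seed, "conditions": {}, "comparisons": {}}
    rng_boot = np.random.default_rng(config.bootstrap_seed)
    for name, cells in summaries.items():
        vip = cells[cells["cell_class"] == "vip"]
        frac_sup = float((vip["dynamics_class"] == "stimulus_suppressed")
                         .mean()) if len(vip) else np.nan
        frac_om = float(vip["omission_responsive"].mean()) \
            if len(vip) else np.nan
        report["conditions"][name] = dict(
            n_cells=len(cells),
            vip_fraction_stimulus_suppressed=frac_sup,
            vip_fraction_omission_responsive=frac_om,
        )
    if len(summaries) >= 2:
        groups = {name: cells[cells["cell_class"] == "vip"]
                  ["stimulus_ramp_index"].to_numpy()
                  for name, cells in summaries.items()}
        if all(np.isfinite(v).sum() >= 2 for v in groups.values()):
            cmp_res = compare_image_sets(groups, "vip_stimulus_ramp_index")
            report["comparisons"]["vip_stimulus_ramp_index"] = dict(
                anova_F=cmp_res.anova_F, anova_p=cmp_res.anova_p,
                corrected_alpha=cmp_res.corrected_alpha,
                pairs=[asdict(p) for p in cmp_res.pairs])
            for name, v in groups.items():
                lo, hi = bootstrap_ci(v, n_boot=config.n_boot, rng=rng_boot)
                report["conditions"][name]["vip_stimulus_ramp_ci"] = [lo, hi]

    (out / "summary.json").write_text(json.dumps(report, indent=1))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report
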