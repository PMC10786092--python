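"""End-to-end study replica: simulate -> preprocess -> RSA -> inference.

``run_pipeline`` executes the full analysis on a synthetic cohort and
writes every stage's outputs (tidy CSV tables, JSON results, a log and a
plain-text summary) into a run directory.  Stages are deterministic under
the global seed; per-stage seeds are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import cluster_test
from .config import DIMENSIONS, SimulationConfig
from .errors import ConfigError
from .mediation import mediate, regress_outcome_on_indicators
from .preprocess import exclude_low_trial_participants, reject_artifact_trials
from .rdm import build_model_rdms
from .rsa import beta_timecourse, window_average
from .traits import (
    extreme_group_compare,
    orthogonalize,
    punishment_outcome,
    score_subcomponents,
)
from .power import log_spaced_sizes, sampling_variability

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("rsamediate.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_participants: int = 40
    artifact_threshold_uv: float = 100.0
    min_trials: int = 10
    indicator_window_ms: tuple[float, float] = (120.0, 160.0)
    analysis_window_ms: tuple[float, float] = (0.0, 600.0)
    cluster_threshold_p: float = 0.05
    n_permutations: int = 10000
    n_boot: int = 10000
    sampling_n_intervals: int = 10
    sampling_n_resamples: int = 200
    seed: int = 0
    write_epochs: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 8:
            raise ConfigError("n_participants must be >= 8 for quartile contrasts")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if self.n_boot < 100:
            raise ConfigError("n_boot must be >= 100")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["indicator_window_ms"] = list(self.indicator_window_ms)
        d["analysis_window_ms"] = list(self.analysis_window_ms)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        data = dict(data)
        if "simulation" in data and not isinstance(data["simulation"], SimulationConfig):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        for key in ("indicator_window_ms", "analysis_window_ms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PipelineResult:
    run_dir: Path
    cohort: pd.DataFrame
    betas: pd.DataFrame
    indicators: pd.DataFrame
    cluster_results: dict
    regression: pd.DataFrame
    mediation: dict
    extreme_groups: dict
    sampling: dict
    summary: str


def _item_mapping(cfg: SimulationConfig) -> dict[str, list[str]]:
    return {
        t: [f"item_{t}_{j + 1}" for j in range(cfg.items_per_factor[t])]
        for t in ("EG", "RI")
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full study replica and write artifacts to ``out_dir``."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, run_dir: Path) -> PipelineResult:
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]

    # stage 1: simulate
    from .simulate import simulate_cohort

    log.info("simulate: n=%d participants", config.n_participants)
    epochs_list, cohort = simulate_cohort(
        config.simulation, config.n_participants, seed=stage_seed[0]
    )
    cohort.to_csv(run_dir / "cohort.csv", index=False)
    if config.write_epochs:
        for ep in epochs_list:
            ep.save(run_dir / "epochs" / ep.participant_id)

    # stage 2: preprocess
    kept = []
    rejected = 0
    for ep in epochs_list:
        ep2, rep = reject_artifact_trials(ep, config.artifact_threshold_uv)
        rejected += rep.trials_rejected
        kept.append(ep2)
    kept, excl_report = exclude_low_trial_participants(kept, config.min_trials)
    log.info(
        "preprocess: %d trials rejected, %d participants excluded",
        rejected,
        len(excl_report.participants_excluded),
    )
    excluded_ids = {pid for pid, _ in excl_report.participants_excluded}
    cohort = cohort[~cohort["participant_id"].isin(excluded_ids)].reset_index(drop=True)

    # stage 3: RSA betas + windowed indicators
    models = build_model_rdms()
    beta_frames = []
    indicator_rows = []
    group = {d: [] for d in DIMENSIONS}
    times = None
    for ep in kept:
        bt = beta_timecourse(ep, models)
        times = bt.times_ms
        beta_frames.append(bt.to_frame())
        ind = window_average(bt, config.indicator_window_ms)
        indicator_rows.append({"participant_id": ep.participant_id, **ind.mean_beta})
        for j, d in enumerate(DIMENSIONS):
            group[d].append(bt.betas[:, j])
    betas = pd.concat(beta_frames, ignore_index=True)
    betas.to_csv(run_dir / "betas.csv", index=False)
    indicators = pd.DataFrame(indicator_rows)
    indicators.to_csv(run_dir / "indicators.csv", index=False)

    # stage 4: cluster permutation per dimension
    cluster_results = {}
    peak_latency = {}
    for d in DIMENSIONS:
        mat = np.vstack(group[d])
        res = cluster_test(
            mat,
            times_ms=times,
            threshold_p=config.cluster_threshold_p,
            n_permutations=config.n_permutations,
            seed=stage_seed[1],
            analysis_window_ms=config.analysis_window_ms,
        )
        cluster_results[d] = res
        lo, hi = config.analysis_window_ms
        mask = (times >= lo) & (times <= hi)
        peak_latency[d] = float(times[mask][np.argmax(mat.mean(axis=0)[mask])])
    (run_dir / "clusters.json").write_text(
        json.dumps({d: r.to_dict() for d, r in cluster_results.items()}, indent=2)
    )

    # stage 5: traits and behavior
    mapping = _item_mapping(config.simulation)
    scores = score_subcomponents(cohort, mapping)
    scores = orthogonalize(scores)
    merged = cohort.merge(scores.drop(columns=["complete"]), on="participant_id")
    merged = merged.merge(indicators, on="participant_id")
    merged["punishment_diff"] = punishment_outcome(merged)
    merged.to_csv(run_dir / "cohort_scored.csv", index=False)

    extreme = {}
    for t in ("EG", "RI"):
        r = extreme_group_compare(merged[f"{t}_orth"], merged["punishment_diff"])
        extreme[t] = {
            "median_low": r.median_low,
            "median_high": r.median_high,
            "statistic": r.statistic,
            "p_value": r.p_value,
        }

    # stage 6: regression and mediation via the race indicator
    regression = regress_outcome_on_indicators(
        merged["punishment_diff"], merged[list(DIMENSIONS)]
    )
    regression.to_csv(run_dir / "regression.csv")
    mediation_results = {}
    for t in ("EG", "RI"):
        res = mediate(
            merged[f"{t}_orth"],
            merged["race"],
            merged["punishment_diff"],
            n_boot=config.n_boot,
            seed=stage_seed[2],
        )
        mediation_results[t] = res.to_dict()
    (run_dir / "mediation.json").write_text(json.dumps(mediation_results, indent=2))

    # stage 7: sampling variability of trait-punishment association
    n = len(merged)
    sizes = log_spaced_sizes(min(25, max(3, n // 2)), n, config.sampling_n_intervals)
    sampling = {}
    for t in ("EG", "RI"):
        curve = sampling_variability(
            merged[f"{t}_orth"],
            merged["punishment_diff"],
            sizes=sizes,
            n_resamples=config.sampling_n_resamples,
            seed=stage_seed[3],
        )
        curve.to_frame().to_csv(run_dir / f"sampling_{t}.csv", index=False)
        sampling[t] = curve

    if config.make_plots:
        _plot_betas(betas, cluster_results, run_dir)

    summary = _summarize(peak_latency, cluster_results, mediation_results, sampling)
    (run_dir / "summary.txt").write_text(summary)
    log.info("pipeline complete")
    return PipelineResult(
        run_dir=run_dir,
        cohort=cohort,
        betas=betas,
        indicators=indicators,
        cluster_results=cluster_results,
        regression=regression,
        mediation=mediation_results,
        extreme_groups=extreme,
        sampling=sampling,
        summary=summary,
    )


def _summarize(peaks, cluster_results, mediation_results, sampling) -> str:
    lines = ["pipeline summary", "================", "", "beta peak latencies (ms):"]
    for d, p in peaks.items():
        lines.append(f"  {d}: {p:.0f}")
    lines.append("")
    lines.append("significant clusters (p < 0.05):")
    for d, res in cluster_results.items():
        sig = res.significant()
        if sig:
            for c in sig:
                lines.append(
                    f"  {d}: {c.start_ms:.0f}-{c.end_ms:.0f} ms, mass {c.mass:.1f}, p={c.p_value:.4f}"
                )
        else:
            lines.append(f"  {d}: none")
    lines.append("")
    lines.append("mediation (trait -> race representation -> punishment):")
    for t, m in mediation_results.items():
        lines.append(
            f"  {t}: indirect {m['indirect']:+.4f} "
            f"CI [{m['ci'][0]:+.4f}, {m['ci'][1]:+.4f}] "
            f"{'significant' if m['significant'] else 'n.s.'}"
        )
    lines.append("")
    lines.append("sampling variability (99% interval width, smallest vs largest n):")
    for t, curve in sampling.items():
        w = curve.width(99)
        lines.append(
            f"  {t}: n={curve.sizes[0]} width {w[0]:.3f} vs n={curve.sizes[-1]} width {w[-1]:.3f}"
        )
    return "\n".join(lines) + "\n"


def _plot_betas(betas: pd.DataFrame, cluster_results, run_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    mean = betas.groupby(["dimension", "time_ms"])["beta"].mean().reset_index()
    y0 = mean["beta"].min()
    for i, d in enumerate(DIMENSIONS):
        sub = mean[mean["dimension"] == d]
        ax.plot(sub["time_ms"], sub["beta"], label=d)
        for c in cluster_results[d].significant():
            ax.hlines(y0 - 0.02 * (i + 1), c.start_ms, c.end_ms, lw=3)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("beta")
    ax.legend()
    fig.tight_layout()
    fig.savefig(run_dir / "betas.png", dpi=120)
    plt.close(fig)
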