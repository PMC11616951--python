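"""End-to-end orchestration: simulate/read traces -> classify -> metrics -> inference.

A single YAML config drives the run; every random stage draws from one
top-level seed through spawned substreams, so a rerun with the same config is
byte-identical.  The effective config is echoed into the output directory
next to the intermediate CSVs and the results JSON.
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

from .bouts import Bout, bouts_to_frame, period_metrics, segment_bouts
from .design import generate_schedule, validate_schedule
from .io import AccelSeries, fill_short_gaps, read_logger_csv, write_logger_csv
from .lmm import ModelSpec, TERMS, fit_lmm, pb_confint, pb_test
from .posture import ClassifierConfig, PostureClassifier
from .simulate import TraceSimParams, simulate_trace

log = logging.getLogger("equirest")


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "equirest_out"
    input_traces: str | None = None  # directory of logger CSVs; None = simulate
    n_horses: int = 10
    n_reps: int = 2
    max_gap_s: int = 5
    classifier: dict = field(default_factory=dict)  # threshold_g, window_samples
    day_trace: dict = field(default_factory=dict)  # TraceSimParams overrides, day segment
    night_trace: dict = field(default_factory=lambda: {"mean_lying_bout_s": 2400.0, "mean_standing_bout_s": 3600.0})
    model: dict = field(default_factory=dict)  # outcome, offset, n_boot, ci_level
    write_posture: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(**self.classifier)

    def model_spec(self) -> ModelSpec:
        opts = {"n_boot": 200, **self.model}
        return ModelSpec(seed=self.seed, **opts)

    def validate(self) -> None:
        self.classifier_config()
        self.model_spec()
        if self.max_gap_s < 0:
            raise ValueError("max_gap_s must be >= 0")
        if self.n_horses < 2 or self.n_reps < 1:
            raise ValueError("need at least 2 horses and 1 repetition")
        TraceSimParams(**{k: v for k, v in self.day_trace.items()})
        TraceSimParams(**{k: v for k, v in self.night_trace.items()})


def simulate_period(
    date: str,
    horse_id: str,
    day_params: TraceSimParams,
    night_params: TraceSimParams,
    rng: np.random.Generator,
) -> tuple[AccelSeries, list[Bout]]:
    """One 24 h horse-period starting 08:00: a day segment (08:00-16:30) and a
    night segment (16:30-08:00 next day) with their own bout processes."""
    start = pd.Timestamp(f"{date} 08:00:00")
    day_len, night_len = 30600, 55800  # 8.5 h + 15.5 h = 24 h
    s_day, t_day = simulate_trace(day_params.replace(duration_s=day_len), horse_id, start, rng)
    s_night, t_night = simulate_trace(
        night_params.replace(duration_s=night_len), horse_id, start + pd.Timedelta(seconds=day_len), rng
    )
    y = np.concatenate([s_day.y_accel, s_night.y_accel])
    series = AccelSeries(horse_id=horse_id, start_time=start, y_accel=y, meta={"simulated": True})
    truth = list(t_day) + [
        Bout(b.state, b.start_idx + day_len, b.end_idx + day_len, b.start, b.end) for b in t_night
    ]
    return series, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts under ``config.out_dir``.

    Stages: schedule -> (simulate or read) traces -> gap-fill -> classify +
    smooth -> segment -> per-window metrics -> mixed model with
    parametric-bootstrap tests and factor-scale CIs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)
    config.to_yaml(out / "config_echo.yaml")
    counts: dict[str, int] = {}

    root = np.random.SeedSequence(config.seed)
    ss_design, ss_trace, ss_model = root.spawn(3)

    schedule = generate_schedule(config.n_horses, config.n_reps, seed=np.random.default_rng(ss_design))
    report = validate_schedule(schedule)
    if not report.passed:
        raise RuntimeError("stage schedule: generated schedule failed validation:\n" + report.summary())
    schedule.to_csv(out / "schedule.csv")
    counts["schedule_periods"] = schedule.n_periods
    log.info("schedule: %d horse-periods", schedule.n_periods)

    clf = PostureClassifier(**{"threshold_g": -0.75, "window_samples": 31, **config.classifier})
    day_params = TraceSimParams(**config.day_trace)
    night_params = TraceSimParams(**config.night_trace)
    rng_trace = np.random.default_rng(ss_trace)

    metrics_rows, bout_frames = [], []
    for _, ent in schedule.entries.iterrows():
        tag = f"{ent.horse_id}_{ent.date}"
        if config.input_traces is None:
            series, _ = simulate_period(ent.date, ent.horse_id, day_params, night_params, rng_trace)
            write_logger_csv(series, out / "traces" / f"{tag}.csv")
        else:
            path = Path(config.input_traces) / f"{tag}.csv"
            if not path.exists():
                raise FileNotFoundError(f"stage read: no trace file for horse-period {tag}: {path}")
            series = read_logger_csv(path, horse_id=str(ent.horse_id))
        series = fill_short_gaps(series, config.max_gap_s)
        posture = clf.classify(series)
        if config.write_posture:
            (out / "posture").mkdir(exist_ok=True)
            posture.to_frame().to_csv(out / "posture" / f"{tag}.csv", index=False)
        df_metrics = period_metrics(posture, base_date=pd.Timestamp(ent.date).date(), condition=ent.condition)
        metrics_rows.append(df_metrics)
        bout_frames.append(bouts_to_frame(segment_bouts(posture), horse_id=str(ent.horse_id)))

    metrics = pd.concat(metrics_rows, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)
    pd.concat(bout_frames, ignore_index=True).to_csv(out / "bouts.csv", index=False)
    counts["metrics_rows"] = len(metrics)
    counts["bout_rows"] = sum(len(b) for b in bout_frames)
    log.info("metrics: %d rows", len(metrics))

    spec = config.model_spec()
    results = run_inference(metrics, spec, seed_seq=ss_model)
    results["stage_counts"] = counts
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    with open(out / "summary.txt", "w") as fh:
        fh.write(format_summary(results))
    return results


def run_inference(metrics: pd.DataFrame, spec: ModelSpec, seed_seq: np.random.SeedSequence | None = None) -> dict:
    """Mixed-model stage: fit, PB tests for all terms, factor-scale CIs."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(spec.seed if spec.seed is not None else 0)
    children = seed_seq.spawn(len(TERMS) + 3)
    fit = fit_lmm(metrics, spec, method="REML")
    tests = {}
    for term, ss in zip(TERMS, children):
        res = pb_test(metrics, spec, term=term, seed=int(ss.generate_state(1)[0] % (2**31)))
        tests[term.lower()] = {k: res[k] for k in ("lrt", "df", "p_value", "p_chi2", "n_boot_used")}
    contrasts = []
    for name, ss in zip(("night_vs_day", "alone_vs_box", "pairs_vs_box"), children[len(TERMS):]):
        cr = pb_confint(metrics, spec, contrast=name, seed=int(ss.generate_state(1)[0] % (2**31)))
        contrasts.append(dataclasses.asdict(cr))
    return {
        "outcome": spec.outcome,
        "offset": fit.offset,
        "fixed_effects": {k: float(v) for k, v in fit.beta.items()},
        "variance_components": {
            "horse": fit.sigma2_horse,
            "date": fit.sigma2_date,
            "residual": fit.sigma2_resid,
        },
        "loglik": fit.loglik,
        "converged": fit.converged,
        "tests": tests,
        "contrasts": contrasts,
    }


def format_summary(results: dict) -> str:
    """Plain-text report in 'by a factor of F [lo-hi]' style."""
    lines = [f"Outcome: {results['outcome']} (log offset c = {results['offset']:.4g})", ""]
    for c in results["contrasts"]:
        lines.append(
            f"  {c['name'].replace('_', ' ')}: by a factor of {c['factor']:.2f} "
            f"[{c['ci_low']:.2f}-{c['ci_high']:.2f}]"
        )
    lines.append("")
    for term, t in results["tests"].items():
        lines.append(f"  {term}: LRT = {t['lrt']:.2f} (df {t['df']}), parametric-bootstrap p = {t['p_value']:.3g}")
    vc = results["variance_components"]
    lines.append("")
    lines.append(
        f"  variance components (log scale): horse {vc['horse']:.3f}, "
        f"date {vc['date']:.3f}, residual {vc['residual']:.3f}"
    )
    return "\n".join(lines) + "\n"
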