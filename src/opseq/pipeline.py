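"""End-to-end orchestration: simulate -> classify -> assay -> stats.

``run_pipeline`` drives one of the canned experiment scripts (or a provided
event log) through the full analysis and writes tidy result tables plus a
machine-readable ``summary.json``. Output is deterministic for a fixed
configuration and seed: tables are written in canonical order and the
summary serializes floats at fixed precision with sorted keys.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, events_io, microstructure, simulator, stats

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("opseq")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``events_path`` (analyze an existing log) or ``script``
    (simulate a cohort) must be provided.
    """

    out_dir: str = "opseq_out"
    script: str | None = None
    events_path: str | None = None
    n_subjects: int = 8
    seed: int = 0
    cutoff_s: float = microstructure.DEFAULT_CUTOFF_S
    peth_window_s: tuple[float, float] = (-5.0, 10.0)
    peth_bin_s: float = 0.5
    sim: simulator.SimConfig = field(default_factory=simulator.SimConfig)
    cno_sim: simulator.SimConfig | None = None

    def __post_init__(self) -> None:
        if (self.script is None) == (self.events_path is None):
            raise ValueError("provide exactly one of script / events_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            raw["sim"] = simulator.SimConfig(**raw["sim"])
        if raw.get("cno_sim"):
            raw["cno_sim"] = simulator.SimConfig(**raw["cno_sim"])
        if "peth_window_s" in raw:
            raw["peth_window_s"] = tuple(raw["peth_window_s"])
        return cls(**raw)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("load")
def _obtain_logs(cfg: RunConfig) -> list[events_io.SessionLog]:
    if cfg.events_path is not None:
        logs = events_io.read_events(cfg.events_path)
    else:
        sim_cfg = cfg.sim
        logs = simulator.simulate_cohort(
            sim_cfg, cfg.n_subjects, cfg.script, seed=cfg.seed, cno_cfg=cfg.cno_sim
        )
    for l in logs:
        events_io.validate_log(l)
    if not logs:
        raise ValueError("no sessions to analyze")
    return logs


@_stage("classify")
def _classify_all(cfg: RunConfig, logs) -> tuple[pd.DataFrame, dict]:
    frames, per_session = [], {}
    for l in logs:
        cl = microstructure.classify_presses(l, cfg.cutoff_s)
        per_session[l.session_id] = cl
        frames.append(microstructure.classified_to_frame(cl, l.subject_id, l.session_id))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, per_session


@_stage("assays")
def _run_assays(cfg: RunConfig, logs, per_session) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    pit_logs = [l for l in logs if l.session_type == "pit_test"]
    if pit_logs:
        period_rows, score_rows = [], []
        for l in pit_logs:
            windows = assays.extract_cs_windows(l)
            table = assays.period_response_table(l, windows, per_session[l.session_id],
                                                 cfg.cutoff_s)
            period_rows.append(table)
            for f in ("all", "with_approach", "without_approach"):
                score_rows.append(
                    {
                        "subject_id": l.subject_id,
                        "session_id": l.session_id,
                        "drug": l.condition_tags.get("drug", "vehicle"),
                        "press_filter": f,
                        "score": assays.pit_score(table, f),
                    }
                )
        out["period_table"] = pd.concat(period_rows, ignore_index=True)
        out["pit_scores"] = pd.DataFrame(score_rows)
    deval_logs = [l for l in logs if l.session_type == "devaluation_test"]
    if deval_logs:
        out["deval_table"] = pd.concat(
            [assays.devaluation_table(l, per_session[l.session_id]) for l in deval_logs],
            ignore_index=True,
        )
    fb_logs = [l for l in logs if l.session_type == "feedback_test"]
    if fb_logs:
        out["feedback_summary"] = assays.feedback_summary(fb_logs, per_session)
    pav_logs = [l for l in logs if l.session_type == "pavlovian"]
    if pav_logs:
        out["pavlovian_scores"] = pd.concat(
            [assays.pavlovian_conditioning_score(l) for l in pav_logs],
            ignore_index=True,
        )
    return out


@_stage("stats")
def _run_stats(cfg: RunConfig, tables) -> dict:
    summary: dict = {}
    if "pit_scores" in tables:
        scores = tables["pit_scores"]
        all_scores = scores[scores["press_filter"] == "all"]
        per_drug = assays.average_repeated_tests(all_scores)
        means = per_drug.groupby("drug")["score"].agg(["mean", "std", "count"])
        summary["pit"] = {
            drug: {
                "mean_score": row["mean"],
                "sd": row["std"] if np.isfinite(row["std"]) else None,
                "n": int(row["count"]),
            }
            for drug, row in means.iterrows()
        }
        for drug, grp in per_drug.groupby("drug"):
            if len(grp) >= 2:
                t = stats.one_sample_t(grp["score"].to_numpy(), 0.0)
                summary["pit"][drug]["one_sample_t_vs_0"] = {
                    "t": t.t, "df": t.df, "p": t.p
                }
        period = tables["period_table"]
        counts = period.groupby(["subject_id", "cs_type", "period"], as_index=False)[
            "press_count"
        ].sum()
        if counts["subject_id"].nunique() >= 2:
            spec = stats.ModelSpec(
                response="press_count", family="poisson_log",
                fixed=("cs_type", "period"), random=("cs_type", "period"),
            )
            fit = stats.fit_count_model(spec, counts)
            summary["press_count_model"] = {
                "converged": fit.converged,
                "coefficients": {
                    k: {"b": c.b, "se": c.se, "p": c.p}
                    for k, c in fit.coefficients.items()
                },
            }
    if "deval_table" in tables:
        dv = tables["deval_table"]
        all_rows = dv[dv["press_type"] == "all"]
        piv = all_rows.pivot_table(
            index="subject_id", columns="lever", values="press_count", aggfunc="sum"
        )
        summary["devaluation"] = {
            "mean_presses_valued": piv["valued"].mean(),
            "mean_presses_devalued": piv["devalued"].mean(),
        }
        props = all_rows.pivot_table(
            index="subject_id", columns="lever",
            values="proportion_with_approach", aggfunc="mean",
        ).dropna()
        if len(props) >= 2:
            t = stats.paired_t(props["valued"], props["devalued"])
            summary["devaluation"]["proportion_paired_t_devalued_minus_valued"] = {
                "t": t.t, "df": t.df, "p": t.p,
                "mean_valued": props["valued"].mean(),
                "mean_devalued": props["devalued"].mean(),
            }
    if "feedback_summary" in tables:
        fb = tables["feedback_summary"]
        summary["feedback"] = {}
        for mode, grp in fb.groupby("feedback_mode"):
            piv = grp.pivot_table(
                index="subject_id", columns="reinforced",
                values="proportion_with_approach", aggfunc="mean",
            )
            entry = {
                "mean_prop_nonreinforced": piv[False].mean() if False in piv else None,
                "mean_prop_reinforced": piv[True].mean() if True in piv else None,
            }
            if True in piv and False in piv:
                paired = piv.dropna()
                if len(paired) >= 2:
                    t = stats.paired_t(
                        stats.sqrt_prop(paired[False]), stats.sqrt_prop(paired[True])
                    )
                    entry["paired_t_sqrt_reinforced_vs_nonreinforced"] = {
                        "t": t.t, "df": t.df, "p": t.p
                    }
            summary["feedback"][mode] = entry
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; write tables and summary under ``cfg.out_dir``.

    Returns the summary dictionary. Deterministic given (config, seed):
    identical runs produce byte-identical ``summary.json``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logs = _obtain_logs(cfg)
    if cfg.n_subjects is not None and len({l.subject_id for l in logs}) < 3:
        log.warning("small cohort (%d subjects): estimates will be noisy",
                    len({l.subject_id for l in logs}))
    events_io.write_events(logs, out_dir / "events.csv")
    classified_frame, per_session = _classify_all(cfg, logs)
    classified_frame.to_csv(out_dir / "classified.csv", index=False)
    tables = _run_assays(cfg, logs, per_session)
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    summary = _run_stats(cfg, tables)
    undefined = 0
    for t in tables.values():
        if "proportion_with_approach" in t:
            undefined += int(t["proportion_with_approach"].isna().sum())
    if undefined:
        log.warning("%d undefined proportions (zero-press cells) excluded", undefined)
    payload = {
        "config": _round_floats(
            {
                **{k: v for k, v in asdict(cfg).items() if k not in ("sim", "cno_sim")},
                "sim": asdict(cfg.sim),
                "cno_sim": asdict(cfg.cno_sim) if cfg.cno_sim else None,
            }
        ),
        "n_sessions": len(logs),
        "n_subjects": len({l.subject_id for l in logs}),
        "n_events": int(sum(len(l.events) for l in logs)),
        "tables": sorted(tables),
        "undefined_proportions": undefined,
        "summary": _round_floats(summary),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload
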