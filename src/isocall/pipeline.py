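"""End-to-end orchestration: simulate -> classify -> filter -> diff -> SRT
-> switch -> panel evaluation, with a machine-readable run summary.

A single global seed is propagated to every stochastic stage through
stage-name-derived sub-seeds, so stages are independently re-runnable yet
deterministic; re-running the whole pipeline with the same config yields
byte-identical artifacts.  Stage wall-times are logged to stderr; the
written summary contains only deterministic content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .classify import calls_to_frame, classify_all
from .diffexp import DiffConfig, differential, overlap_decomposition, results_to_frame
from .filters import FilterConfig, run_filter_cascade
from .io import (
    FastaGenome,
    read_expression,
    read_gtf,
    read_junction_support,
    write_gtf,
)
from .panel import PanelEvalConfig, evaluate_panel
from .simulate import SimulationConfig, simulate
from .srt import SrtConfig, call_metastasis_srt, call_srt, calls_to_frame as srt_frame
from .switching import detect_switches, events_to_frame, isoform_fractions

logger = logging.getLogger("isocall")


@dataclass
class PipelineConfig:
    out_dir: str = "isocall_run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    srt: SrtConfig = field(default_factory=SrtConfig)
    panel: PanelEvalConfig = field(default_factory=PanelEvalConfig)

    @staticmethod
    def from_toml(path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = PipelineConfig()
        for key in ("out_dir", "seed"):
            if key in data:
                setattr(cfg, key, data[key])
        for section, target in (
            ("sim", cfg.sim),
            ("filter", cfg.filter),
            ("diff", cfg.diff),
            ("srt", cfg.srt),
            ("panel", cfg.panel),
        ):
            for k, v in data.get(section, {}).items():
                if not hasattr(target, k):
                    raise KeyError(f"unknown option {k!r} in [{section}]")
                current = getattr(target, k)
                if isinstance(current, tuple):
                    v = tuple(v)
                setattr(target, k, v)
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunSummary:
    seed: int
    config: dict
    category_tally: dict[str, int]
    filter_rule_counts: dict[str, int]
    n_merged: int
    n_final_transcripts: int
    n_det: int
    n_deg: int
    overlap: dict[str, int]
    n_srt: int
    n_met_srt: int
    n_switch_genes: int
    panel_auc_train_cv: float | None
    panel_auc_test: float | None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> RunSummary:
    """Run every stage on a synthetic study and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Timer()

    sim_dir = out / "data"
    with _stage("simulate"):
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        simulate(sim_cfg, sim_dir)

    with _stage("classify"):
        ref = read_gtf(sim_dir / "reference.gtf", kind="reference")
        per_sample = {}
        for path in sorted(sim_dir.glob("isoseq_*.gtf")):
            sample = path.stem.replace("isoseq_", "")
            per_sample[sample] = read_gtf(path, kind="query")
        unique: dict[str, Any] = {}
        for models in per_sample.values():
            for m in models:
                unique.setdefault(m.transcript_id, m)
        calls, tally = classify_all(
            [unique[k] for k in sorted(unique)], ref
        )
        calls_to_frame(calls).to_csv(
            out / "calls.tsv", sep="\t", index=False
        )

    with _stage("filter"):
        genome = FastaGenome(sim_dir / "genome.fa")
        support = read_junction_support(sorted(sim_dir.glob("junctions_*.tsv")))
        cascade = run_filter_cascade(per_sample, ref, support, genome, config.filter)
        write_gtf(cascade.final_models, out / "final_transcripts.gtf")
        report_rows = []
        for sample in sorted(cascade.junction_report):
            for stage_report in (
                cascade.junction_report[sample],
                cascade.intrapriming_report[sample],
                cascade.ism_report[sample],
            ):
                for (smp, tx), rule in sorted(stage_report.status.items()):
                    report_rows.append(
                        {
                            "sample": smp,
                            "transcript_id": tx,
                            "rule": stage_report.rule,
                            "failed": rule is not None,
                        }
                    )
        pd.DataFrame(report_rows).to_csv(out / "filter_report.tsv", sep="\t", index=False)

    with _stage("diff"):
        matrix = read_expression(sim_dir / "expression.tsv", sim_dir / "groups.tsv")
        tx2gene = dict(
            pd.read_csv(sim_dir / "tx2gene.tsv", sep="\t").itertuples(index=False)
        )
        det = differential(
            matrix, "tumour", "normal", level="transcript", calls=calls, cfg=config.diff
        )
        deg = differential(
            matrix,
            "tumour",
            "normal",
            level="gene",
            tx2gene=tx2gene,
            calls=calls,
            cfg=config.diff,
        )
        decomposition = overlap_decomposition(det, deg, tx2gene)
        results_to_frame(det).to_csv(out / "det.tsv", sep="\t", index=False)
        results_to_frame(deg).to_csv(out / "deg.tsv", sep="\t", index=False)
        with open(out / "overlap.json", "w") as fh:
            json.dump(decomposition.counts, fh, indent=2, sort_keys=True)
            fh.write("\n")

    with _stage("srt"):
        srt_calls = call_srt(matrix, "tumour", "normal", config.srt)
        met_calls = call_metastasis_srt(matrix, "metastasis", "primary", cfg=config.srt)
        srt_frame(srt_calls).to_csv(out / "srt.tsv", sep="\t", index=False)
        srt_frame(met_calls).to_csv(out / "srt_met.tsv", sep="\t", index=False)

    with _stage("switch"):
        events = detect_switches(det, tx2gene)
        events_to_frame(events).to_csv(out / "switches.tsv", sep="\t", index=False)
        fractions = isoform_fractions(matrix, tx2gene)
        fractions.to_csv(out / "isoform_fractions.tsv", sep="\t", float_format="%.6f")

    panel_auc_cv = panel_auc_test = None
    panel_ids = sorted(c.transcript_id for c in met_calls if c.is_srt)
    if len(panel_ids) >= 1:
        with _stage("panel"):
            met_samples = matrix.samples_in("metastasis")
            primary_samples = matrix.samples_in("primary")
            labels = pd.Series(
                [1] * len(met_samples) + [0] * len(primary_samples),
                index=met_samples + primary_samples,
            )
            panel_cfg = dataclasses.replace(
                config.panel, seed=stage_seed(config.seed, "panel")
            )
            result = evaluate_panel(matrix, panel_ids, labels, panel_cfg)
            panel_auc_cv = round(result.auc_train_cv, 6)
            panel_auc_test = round(result.auc_test, 6)
            with open(out / "panel_eval.json", "w") as fh:
                json.dump(
                    {
                        "panel": panel_ids,
                        "auc_train_cv": panel_auc_cv,
                        "auc_test": panel_auc_test,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
                fh.write("\n")

    summary = RunSummary(
        seed=config.seed,
        config=_config_dict(config),
        category_tally={k: int(v) for k, v in sorted(tally.items())},
        filter_rule_counts={k: int(v) for k, v in sorted(cascade.rule_counts.items())},
        n_merged=len(cascade.merged),
        n_final_transcripts=len(cascade.final_models),
        n_det=sum(r.is_significant for r in det),
        n_deg=sum(r.is_significant for r in deg),
        overlap=decomposition.counts,
        n_srt=sum(c.is_srt for c in srt_calls),
        n_met_srt=sum(c.is_srt for c in met_calls),
        n_switch_genes=len(events),
        panel_auc_train_cv=panel_auc_cv,
        panel_auc_test=panel_auc_test,
    )
    with open(out / "run_summary.json", "w") as fh:
        fh.write(summary.to_json())
    for stage, dt in timings.items():
        logger.info("timing %s: %.2fs", stage, dt)
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, sort_keys=True, default=list))
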