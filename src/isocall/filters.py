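"""Post-classification artifact filters and the cross-sample merge.

The cascade mirrors the order evidence becomes available: per-sample models
are classified, required to have short-read support at every junction,
screened for intrapriming (a genomic adenine tract directly downstream of
the 3' end, the signature of oligo-dT mispriming), ISM models truncated
only at the 3' end are dropped as degradation artifacts, surviving models
are merged into a non-redundant set by junction-chain identity, and finally
models seen in fewer than the required number of biological replicates are
removed.

Full-splice matches are exempt from the intrapriming rule: a chain already
present in the annotation is accepted as-is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .classify import StructuralCall, classify_all
from .io import GenomeSource
from .models import GenomicInterval, ReferenceAnnotation, TranscriptModel
from .models import JunctionSupportTable

RULE_JUNCTION = "junction_support"
RULE_INTRAPRIMING = "intrapriming"
RULE_ISM_3P = "ism_3p_truncated"
RULE_REPLICATES = "min_replicates"


@dataclass
class FilterConfig:
    """Thresholds of the artifact-filter cascade.

    min_junction_reads:
        pooled short-read support every junction of a multi-exon model must
        reach (default 1: the junction must merely be observed).
    polyA_window / polyA_min_A:
        a model fails the intrapriming rule when the ``polyA_window`` bases
        genomically downstream of its 3' end contain ``polyA_min_A`` or more
        adenines on the transcript strand (defaults 20 bp / 16 A).
    min_replicates:
        number of distinct samples a merged model must have been seen in
        (default 2).
    filter_ism_ends:
        drop ISM models whose missing region is at the 3' end only.
    """

    min_junction_reads: int = 1
    polyA_window: int = 20
    polyA_min_A: int = 16
    min_replicates: int = 2
    filter_ism_ends: bool = True

    def __post_init__(self) -> None:
        if self.polyA_min_A > self.polyA_window:
            raise ValueError("polyA_min_A cannot exceed polyA_window")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass
class FilterReport:
    """Pass/fail status per model with the first failing rule."""

    rule: str
    status: dict[tuple[str | None, str], str | None] = field(default_factory=dict)
    flags: dict[tuple[str | None, str], str] = field(default_factory=dict)

    @staticmethod
    def key(model: TranscriptModel) -> tuple[str | None, str]:
        return (model.source_sample, model.transcript_id)

    def record(self, model: TranscriptModel, failed: bool, flag: str | None = None) -> None:
        self.status[self.key(model)] = self.rule if failed else None
        if flag:
            self.flags[self.key(model)] = flag

    def passed(self, model: TranscriptModel) -> bool:
        return self.status[self.key(model)] is None

    def pass_set(self, models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
        return [m for m in models if self.passed(m)]

    @property
    def counts(self) -> Counter:
        return Counter(
            "pass" if rule is None else rule for rule in self.status.values()
        )


def _calls_by_key(
    models: Sequence[TranscriptModel], calls: Sequence[StructuralCall]
) -> dict[str, StructuralCall]:
    by_id = {c.transcript_id: c for c in calls}
    for m in models:
        if m.transcript_id not in by_id:
            raise ValueError(f"model {m.transcript_id} has no structural call")
    return by_id


def junction_support_filter(
    models: Sequence[TranscriptModel],
    calls: Sequence[StructuralCall],
    support: JunctionSupportTable,
    cfg: FilterConfig | None = None,
) -> FilterReport:
    """Keep multi-exon models only if every junction has read support.

    Mono-exon models pass vacuously (they have no junctions to support).
    """
    cfg = cfg or FilterConfig()
    _calls_by_key(models, calls)
    report = FilterReport(rule=RULE_JUNCTION)
    for model in models:
        failed = any(
            support.get(j) < cfg.min_junction_reads for j in model.junction_chain()
        )
        report.record(model, failed)
    return report


def downstream_a_count(
    model: TranscriptModel, genome: GenomeSource, window: int = 20
) -> tuple[int, bool]:
    """Adenines (on the transcript strand) in the window downstream of the TTS.

    Returns (count, truncated): the window is clipped at sequence bounds and
    flagged when clipping occurred.
    """
    seq_len = genome.length(model.seq_name)
    if model.strand == "+":
        start, end = model.end, min(model.end + window, seq_len)
        base = "A"
    else:
        start, end = max(model.start - window, 0), model.start
        base = "T"  # A on the transcript strand
    truncated = (end - start) < window
    if end <= start:
        return 0, truncated
    seq = genome.fetch(model.seq_name, start, end).upper()
    return seq.count(base), truncated


def intrapriming_filter(
    models: Sequence[TranscriptModel],
    calls: Sequence[StructuralCall],
    genome: GenomeSource,
    cfg: FilterConfig | None = None,
) -> FilterReport:
    """Remove non-FSM models with an adenine tract downstream of the TTS.

    FSM models always pass; for every other category the model fails when
    the ``polyA_window`` bases genomically downstream of its 3' end contain
    at least ``polyA_min_A`` adenines on the transcript strand.
    """
    cfg = cfg or FilterConfig()
    by_id = _calls_by_key(models, calls)
    report = FilterReport(rule=RULE_INTRAPRIMING)
    for model in models:
        call = by_id[model.transcript_id]
        if call.category == "FSM":
            report.record(model, failed=False)
            continue
        count, truncated = downstream_a_count(model, genome, cfg.polyA_window)
        report.record(
            model,
            failed=count >= cfg.polyA_min_A,
            flag="truncated_window" if truncated else None,
        )
    return report


def ism_end_filter(
    models: Sequence[TranscriptModel],
    calls: Sequence[StructuralCall],
    cfg: FilterConfig | None = None,
) -> FilterReport:
    """Drop ISM models whose missing region is at the 3' end only.

    3'-truncated incomplete matches are the canonical RNA-degradation /
    incomplete reverse-transcription artifact.  Disabled when
    ``cfg.filter_ism_ends`` is false.
    """
    cfg = cfg or FilterConfig()
    by_id = _calls_by_key(models, calls)
    report = FilterReport(rule=RULE_ISM_3P)
    for model in models:
        call = by_id[model.transcript_id]
        failed = (
            cfg.filter_ism_ends
            and call.category == "ISM"
            and call.diagnostics.get("missing_3p", False)
            and not call.diagnostics.get("missing_5p", False)
        )
        report.record(model, failed)
    return report


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def merge_nonredundant(
    per_sample_models: Mapping[str, Sequence[TranscriptModel]],
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Merge per-sample models into a non-redundant set with occurrence counts.

    Multi-exon models with identical junction chains are merged into one
    record whose terminal-exon ends are the outermost observed ends.
    Mono-exon models merge when their reciprocal overlap is >= 50% on the
    same strand.  The occurrence count of a merged record is the number of
    distinct samples contributing to it; the record keeps the
    lexicographically smallest contributing transcript id.
    """
    multi_groups: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
    mono: list[tuple[str, TranscriptModel]] = []
    for sample in sorted(per_sample_models):
        for model in per_sample_models[sample]:
            if model.is_mono_exon:
                mono.append((sample, model))
            else:
                multi_groups.setdefault(model.chain_key(), []).append((sample, model))

    merged: list[TranscriptModel] = []
    counts: dict[str, int] = {}

    for key in sorted(multi_groups):
        members = multi_groups[key]
        rep_id = min(m.transcript_id for _, m in members)
        start = min(m.start for _, m in members)
        end = max(m.end for _, m in members)
        template = members[0][1]
        exons = list(template.exons)
        exons[0] = GenomicInterval(
            template.seq_name, start, exons[0].end, template.strand
        )
        exons[-1] = GenomicInterval(
            template.seq_name, exons[-1].start, end, template.strand
        )
        gene_ids = {m.gene_id for _, m in members if m.gene_id is not None}
        merged.append(
            TranscriptModel(
                transcript_id=rep_id,
                exons=tuple(exons),
                gene_id=min(gene_ids) if gene_ids else None,
            )
        )
        counts[rep_id] = len({s for s, _ in members})

    # mono-exon: single-linkage clustering on >=50% reciprocal overlap
    parent = list(range(len(mono)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(mono)):
        for k in range(i + 1, len(mono)):
            a, b = mono[i][1], mono[k][1]
            if a.seq_name != b.seq_name or a.strand != b.strand:
                continue
            if _reciprocal_overlap(a, b) >= 0.5:
                parent[find(i)] = find(k)

    clusters: dict[int, list[tuple[str, TranscriptModel]]] = {}
    for i, item in enumerate(mono):
        clusters.setdefault(find(i), []).append(item)
    for root in sorted(clusters, key=lambda r: min(m.transcript_id for _, m in clusters[r])):
        members = clusters[root]
        rep_id = min(m.transcript_id for _, m in members)
        start = min(m.start for _, m in members)
        end = max(m.end for _, m in members)
        template = members[0][1]
        gene_ids = {m.gene_id for _, m in members if m.gene_id is not None}
        merged.append(
            TranscriptModel(
                transcript_id=rep_id,
                exons=(GenomicInterval(template.seq_name, start, end, template.strand),),
                gene_id=min(gene_ids) if gene_ids else None,
            )
        )
        counts[rep_id] = len({s for s, _ in members})

    return merged, counts


def replicate_filter(
    merged: Sequence[TranscriptModel],
    counts: Mapping[str, int],
    cfg: FilterConfig | None = None,
) -> list[TranscriptModel]:
    """Keep merged models detected in at least ``min_replicates`` samples."""
    cfg = cfg or FilterConfig()
    return [m for m in merged if counts[m.transcript_id] >= cfg.min_replicates]


@dataclass
class CascadeResult:
    """Everything the filter cascade produced, per stage."""

    calls: dict[str, list[StructuralCall]]
    junction_report: dict[str, FilterReport]
    intrapriming_report: dict[str, FilterReport]
    ism_report: dict[str, FilterReport]
    merged: list[TranscriptModel]
    occurrence_counts: dict[str, int]
    final_models: list[TranscriptModel]

    @property
    def rule_counts(self) -> Counter:
        total: Counter = Counter()
        for reports in (self.junction_report, self.intrapriming_report, self.ism_report):
            for report in reports.values():
                total.update(
                    rule for rule in report.status.values() if rule is not None
                )
        total[RULE_REPLICATES] = len(self.merged) - len(self.final_models)
        return total


def run_filter_cascade(
    per_sample_models: Mapping[str, Sequence[TranscriptModel]],
    ref: ReferenceAnnotation,
    support: JunctionSupportTable,
    genome: GenomeSource,
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """classify -> junction support -> intrapriming -> ISM ends -> merge -> replicates."""
    cfg = cfg or FilterConfig()
    calls: dict[str, list[StructuralCall]] = {}
    junction_reports: dict[str, FilterReport] = {}
    intra_reports: dict[str, FilterReport] = {}
    ism_reports: dict[str, FilterReport] = {}
    survivors: dict[str, list[TranscriptModel]] = {}

    for sample in sorted(per_sample_models):
        models = [
            TranscriptModel(
                transcript_id=m.transcript_id,
                exons=m.exons,
                gene_id=m.gene_id,
                source_sample=sample,
            )
            for m in per_sample_models[sample]
        ]
        sample_calls, _ = classify_all(models, ref)
        calls[sample] = sample_calls

        jr = junction_support_filter(models, sample_calls, support, cfg)
        junction_reports[sample] = jr
        kept = jr.pass_set(models)

        ir = intrapriming_filter(kept, sample_calls, genome, cfg)
        intra_reports[sample] = ir
        kept = ir.pass_set(kept)

        er = ism_end_filter(kept, sample_calls, cfg)
        ism_reports[sample] = er
        survivors[sample] = er.pass_set(kept)

    merged, counts = merge_nonredundant(survivors)
    final = replicate_filter(merged, counts, cfg)
    return CascadeResult(
        calls=calls,
        junction_report=junction_reports,
        intrapriming_report=intra_reports,
        ism_report=ism_reports,
        merged=merged,
        occurrence_counts=counts,
        final_models=final,
    )
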