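"""Structural classification of query transcript models against a reference.

Every query transcript receives exactly one category describing how its
splice-junction chain relates to the reference transcriptome:

* ``FSM`` (full-splice match) — the chain equals a reference transcript's
  chain exactly.  Terminal exon ends are ignored; end variation is the
  business of the filter stage.
* ``ISM`` (incomplete-splice match) — the chain is a contiguous,
  order-preserving sub-chain of some reference chain (the query lacks the
  5' region, the 3' region, or both).
* ``NIC`` (novel in catalogue) — every splice site is annotated, but the
  combination has never been catalogued in one transcript.
* ``NNC`` (novel not in catalogue) — at least one splice site is absent
  from the reference.
* ``antisense`` — overlaps annotated genes only on the opposite strand.
* ``intergenic`` — overlaps no annotated gene.
* ``other_genic`` — mono-exon query inside a same-strand gene span but not
  within any annotated exon (e.g. purely intronic).

Splice-site identity is exact (0 bp tolerance) and strand-aware: a donor on
the plus strand never matches an acceptor at the same coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import Junction, ReferenceAnnotation, TranscriptModel

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "antisense",
    "intergenic",
    "other_genic",
)

#: The five-way reporting convention collapses the non-model categories.
OTHERS = ("antisense", "intergenic", "other_genic")


@dataclass
class StructuralCall:
    """The category assigned to one query transcript, with diagnostics."""

    transcript_id: str
    category: str
    assigned_gene: str | None = None
    matched_reference_transcript: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("FSM", "ISM") and not self.matched_reference_transcript:
            raise ValueError(f"{self.category} call requires a matched transcript")
        if self.category == "intergenic" and self.assigned_gene is not None:
            raise ValueError("intergenic calls carry no assigned gene")


def _find_contiguous_subchain(
    chain: Sequence[Junction], ref_chain: Sequence[Junction]
) -> int | None:
    """Offset at which ``chain`` occurs contiguously in ``ref_chain``, else None."""
    n, m = len(ref_chain), len(chain)
    for offset in range(n - m + 1):
        if tuple(ref_chain[offset : offset + m]) == tuple(chain):
            return offset
    return None


def _assign_gene_by_junctions(
    query: TranscriptModel, ref: ReferenceAnnotation
) -> str | None:
    """Same-strand gene sharing the most junctions; ties broken by exonic
    overlap bp, then lexicographic gene id."""
    candidates = ref.overlapping_genes(
        query.seq_name, query.start, query.end, strand=query.strand
    )
    if not candidates:
        return None
    chain = set(query.junction_chain())
    best = None
    for gene in candidates:
        shared = 0
        for tx in ref.gene_transcripts(gene.gene_id):
            shared = max(shared, len(chain & set(tx.junction_chain())))
        overlap = _exonic_overlap_bp(query, ref, gene.gene_id)
        key = (-shared, -overlap, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, gene.gene_id)
    return best[1]


def _exonic_overlap_bp(
    query: TranscriptModel, ref: ReferenceAnnotation, gene_id: str
) -> int:
    total = 0
    for tx in ref.gene_transcripts(gene_id):
        bp = 0
        for qe in query.exons:
            for re_ in tx.exons:
                bp += max(0, min(qe.end, re_.end) - max(qe.start, re_.start))
        total = max(total, bp)
    return total


def _antisense_gene(query: TranscriptModel, ref: ReferenceAnnotation) -> str | None:
    opposite = "-" if query.strand == "+" else "+"
    candidates = ref.overlapping_genes(
        query.seq_name, query.start, query.end, strand=opposite
    )
    if not candidates:
        return None
    best = None
    for gene in candidates:
        overlap = _exonic_overlap_bp(query, ref, gene.gene_id)
        key = (-overlap, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, gene.gene_id)
    return best[1]


def _classify_multi_exon(
    query: TranscriptModel, ref: ReferenceAnnotation
) -> StructuralCall:
    chain = query.junction_chain()

    # (1) exact chain match -> FSM
    matches = ref.chain_matches(query)
    if matches:
        matched = matches[0]
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="FSM",
            assigned_gene=ref.transcripts[matched].gene_id,
            matched_reference_transcript=matched,
            diagnostics={"novel_site_count": 0, "novel_junction_count": 0},
        )

    # (2) contiguous sub-chain of a reference chain -> ISM
    candidates = sorted(set(ref.transcripts_containing_junction(chain[0])))
    for tx_id in candidates:
        ref_chain = ref.transcripts[tx_id].junction_chain()
        offset = _find_contiguous_subchain(chain, ref_chain)
        if offset is None:
            continue
        missing_left = offset > 0
        missing_right = offset + len(chain) < len(ref_chain)
        if query.strand == "+":
            missing_5p, missing_3p = missing_left, missing_right
        else:
            missing_5p, missing_3p = missing_right, missing_left
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="ISM",
            assigned_gene=ref.transcripts[tx_id].gene_id,
            matched_reference_transcript=tx_id,
            diagnostics={
                "novel_site_count": 0,
                "novel_junction_count": 0,
                "subchain_offset": offset,
                "missing_5p": missing_5p,
                "missing_3p": missing_3p,
            },
        )

    novel_sites = {
        site
        for j in chain
        for site in j.sites()
        if site not in ref.splice_site_index
    }
    novel_junctions = [j for j in chain if j not in ref.junction_index]
    diagnostics = {
        "novel_site_count": len(novel_sites),
        "novel_junction_count": len(novel_junctions),
    }

    # (3) all splice sites annotated -> NIC
    if not novel_sites:
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="NIC",
            assigned_gene=_assign_gene_by_junctions(query, ref),
            diagnostics=diagnostics,
        )

    # (4) novel site over a same-strand gene -> NNC
    same_strand = ref.overlapping_genes(
        query.seq_name, query.start, query.end, strand=query.strand
    )
    if same_strand:
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="NNC",
            assigned_gene=_assign_gene_by_junctions(query, ref),
            diagnostics=diagnostics,
        )

    # (5) only opposite-strand overlap -> antisense; (6) none -> intergenic
    anti = _antisense_gene(query, ref)
    if anti is not None:
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="antisense",
            assigned_gene=anti,
            diagnostics=diagnostics,
        )
    return StructuralCall(
        transcript_id=query.transcript_id,
        category="intergenic",
        diagnostics=diagnostics,
    )


def _classify_mono_exon(
    query: TranscriptModel, ref: ReferenceAnnotation
) -> StructuralCall:
    # FSM: identical interval of a mono-exon reference transcript
    matches = ref.mono_exon_matches(query)
    if matches:
        matched = matches[0]
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="FSM",
            assigned_gene=ref.transcripts[matched].gene_id,
            matched_reference_transcript=matched,
            diagnostics={"novel_site_count": 0, "novel_junction_count": 0},
        )
    # ISM: contained within a same-strand annotated exon
    interval = query.exons[0]
    containing: list[tuple[str, str]] = []
    for gene in ref.overlapping_genes(
        query.seq_name, query.start, query.end, strand=query.strand
    ):
        for tx in ref.gene_transcripts(gene.gene_id):
            for exon in tx.exons:
                if exon.start <= interval.start and interval.end <= exon.end:
                    containing.append((tx.transcript_id, gene.gene_id))
    if containing:
        tx_id, gene_id = min(containing)
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="ISM",
            assigned_gene=gene_id,
            matched_reference_transcript=tx_id,
            diagnostics={
                "novel_site_count": 0,
                "novel_junction_count": 0,
                "missing_5p": True,
                "missing_3p": True,
            },
        )
    same_strand = ref.overlapping_genes(
        query.seq_name, query.start, query.end, strand=query.strand
    )
    if same_strand:
        best = None
        for gene in same_strand:
            overlap = _exonic_overlap_bp(query, ref, gene.gene_id)
            key = (-overlap, gene.gene_id)
            if best is None or key < best[0]:
                best = (key, gene.gene_id)
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="other_genic",
            assigned_gene=best[1],
        )
    anti = _antisense_gene(query, ref)
    if anti is not None:
        return StructuralCall(
            transcript_id=query.transcript_id,
            category="antisense",
            assigned_gene=anti,
        )
    return StructuralCall(transcript_id=query.transcript_id, category="intergenic")


def classify(query: TranscriptModel, ref: ReferenceAnnotation) -> StructuralCall:
    """Assign one structural category to a query transcript model."""
    if query.is_mono_exon:
        return _classify_mono_exon(query, ref)
    return _classify_multi_exon(query, ref)


def classify_all(
    queries: Iterable[TranscriptModel], ref: ReferenceAnnotation
) -> tuple[list[StructuralCall], Counter]:
    """Classify every query; returns the calls and a category tally."""
    calls: list[StructuralCall] = []
    seen: set[str] = set()
    for query in queries:
        if query.transcript_id in seen:
            raise ValueError(f"duplicate query transcript id {query.transcript_id}")
        seen.add(query.transcript_id)
        calls.append(classify(query, ref))
    tally = Counter(call.category for call in calls)
    return calls, tally


def calls_to_frame(calls: Sequence[StructuralCall]):
    """Tabular view of structural calls (one row per query transcript)."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "category": c.category,
                "assigned_gene": c.assigned_gene if c.assigned_gene else "",
                "matched_ref": c.matched_reference_transcript or "",
                "novel_site_count": c.diagnostics.get("novel_site_count", 0),
                "novel_junction_count": c.diagnostics.get("novel_junction_count", 0),
                "subchain_offset": c.diagnostics.get("subchain_offset", ""),
                "missing_5p": c.diagnostics.get("missing_5p", ""),
                "missing_3p": c.diagnostics.get("missing_3p", ""),
            }
        )
    return pd.DataFrame(rows)
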