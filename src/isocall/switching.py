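"""Isoform-switch detection and per-sample isoform fractions.

A gene undergoes an isoform switch between conditions when at least one of
its transcript variants is significantly upregulated while another is
significantly downregulated (significance thresholds are exactly those of
the differential-transcript test: |log2FC| > 1, FDR < 0.05 by default).
Genes with a single tested transcript are ineligible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import DiffResult
from .io import ExpressionMatrix


@dataclass
class SwitchEvent:
    gene_id: str
    up_transcripts: list[str]
    down_transcripts: list[str]
    stats: dict[str, tuple[float, float]]  # transcript -> (log2_fc, fdr)


def detect_switches(
    det_results: Sequence[DiffResult],
    tx2gene: Mapping[str, str],
) -> list[SwitchEvent]:
    """One event per gene with >= 1 significant-up and >= 1 significant-down transcript."""
    by_gene: dict[str, list[DiffResult]] = {}
    for r in det_results:
        if r.feature_id not in tx2gene:
            raise KeyError(f"transcript {r.feature_id} missing from tx2gene map")
        by_gene.setdefault(tx2gene[r.feature_id], []).append(r)

    events = []
    for gene_id in sorted(by_gene):
        tested = by_gene[gene_id]
        if len(tested) < 2:
            continue
        up = sorted(
            r.feature_id for r in tested if r.is_significant and r.log2_fc > 0
        )
        down = sorted(
            r.feature_id for r in tested if r.is_significant and r.log2_fc < 0
        )
        if up and down:
            stats = {
                r.feature_id: (r.log2_fc, r.fdr)
                for r in tested
                if r.feature_id in set(up) | set(down)
            }
            events.append(
                SwitchEvent(
                    gene_id=gene_id,
                    up_transcripts=up,
                    down_transcripts=down,
                    stats=stats,
                )
            )
    return events


def isoform_fractions(
    matrix: ExpressionMatrix,
    tx2gene: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample transcript TPM / gene TPM; NaN where the gene TPM is 0.

    For every gene and sample with nonzero gene expression the fractions of
    its member transcripts sum to 1.
    """
    missing = [t for t in matrix.transcript_ids if t not in tx2gene]
    if missing:
        raise KeyError(f"transcripts missing from tx2gene map: {missing[:5]}")
    genes = pd.Series({t: tx2gene[t] for t in matrix.transcript_ids})
    gene_sums = matrix.values.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = matrix.values / gene_sums
    return fractions.where(gene_sums > 0)


def events_to_frame(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "up_transcripts": [",".join(e.up_transcripts) for e in events],
            "down_transcripts": [",".join(e.down_transcripts) for e in events],
        }
    )
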