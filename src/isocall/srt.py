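"""Specific-RNA-transcript (SRT) callers.

A tumour SRT is a transcript expressed essentially exclusively in tumours:

(i)  its median TPM across tumour samples is at least ``fold_threshold``
     (default 10) times the *maximum* TPM observed across all normal
     samples — with the guard that the tumour median itself is positive,
     so all-zero transcripts are never called; and
(ii) it is expressed (TPM > 0.5) in more than 5% of tumour samples.

The metastasis-specific variant compares group medians with a pseudocount
(criterion strictly greater than the fold threshold) and applies the same
prevalence rule over metastasis samples; an optional third criterion
requires near-silence in normal tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class SrtConfig:
    fold_threshold: float = 10.0
    prevalence_tpm: float = 0.5
    prevalence_fraction: float = 0.05  # strict ">"
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not (0 <= self.prevalence_fraction < 1):
            raise ValueError("prevalence_fraction must be in [0, 1)")


@dataclass
class SrtCall:
    transcript_id: str
    median_tumour: float
    max_normal: float
    prevalence: float
    passes_i: bool
    passes_ii: bool

    @property
    def is_srt(self) -> bool:
        return self.passes_i and self.passes_ii


def _prevalence(tumour: np.ndarray, cfg: SrtConfig) -> float:
    return float((tumour > cfg.prevalence_tpm).sum() / tumour.shape[0])


def call_srt(
    matrix: ExpressionMatrix,
    tumour_group: str,
    normal_group: str,
    cfg: SrtConfig | None = None,
    transcripts: Sequence[str] | None = None,
) -> list[SrtCall]:
    """Call tumour-exclusive transcripts (median over max rule).

    Criterion (i) compares the tumour median against ``fold_threshold``
    times the maximum over all normal samples ("at least", i.e. >=), with
    a positive-median guard; criterion (ii) requires TPM above
    ``prevalence_tpm`` in strictly more than ``prevalence_fraction`` of
    tumour samples.
    """
    cfg = cfg or SrtConfig()
    tumour = matrix.group_values(tumour_group)
    normal = matrix.group_values(normal_group)
    rows = _select_rows(matrix, transcripts)

    calls = []
    for tx in rows:
        t = tumour.loc[tx].to_numpy(dtype=float)
        n = normal.loc[tx].to_numpy(dtype=float)
        med_t = float(np.median(t))
        max_n = float(n.max())
        passes_i = med_t > 0 and med_t >= cfg.fold_threshold * max_n
        prevalence = _prevalence(t, cfg)
        passes_ii = prevalence > cfg.prevalence_fraction
        calls.append(
            SrtCall(
                transcript_id=tx,
                median_tumour=med_t,
                max_normal=max_n,
                prevalence=prevalence,
                passes_i=passes_i,
                passes_ii=passes_ii,
            )
        )
    return calls


def call_metastasis_srt(
    matrix: ExpressionMatrix,
    metastasis_group: str,
    primary_group: str,
    normal_groups: Sequence[str] | None = None,
    cfg: SrtConfig | None = None,
    require_normal_silent: bool = False,
    transcripts: Sequence[str] | None = None,
) -> list[SrtCall]:
    """Call metastasis-specific transcripts (median fold change > threshold).

    Criterion (i) is a strict ``>`` on the pseudocounted ratio of group
    medians; criterion (ii) is the prevalence rule over metastasis samples.
    When ``require_normal_silent`` is set and ``normal_groups`` given, the
    transcript must additionally stay below ``prevalence_tpm`` in every
    normal sample.
    """
    cfg = cfg or SrtConfig()
    met = matrix.group_values(metastasis_group)
    primary = matrix.group_values(primary_group)
    normals = None
    if normal_groups:
        cols: list[str] = []
        for g in normal_groups:
            cols.extend(matrix.samples_in(g))
        if not cols:
            raise ValueError("normal_groups matched no samples")
        normals = matrix.values[cols]
    rows = _select_rows(matrix, transcripts)

    calls = []
    for tx in rows:
        m = met.loc[tx].to_numpy(dtype=float)
        p = primary.loc[tx].to_numpy(dtype=float)
        med_m = float(np.median(m))
        med_p = float(np.median(p))
        ratio = (med_m + cfg.pseudocount) / (med_p + cfg.pseudocount)
        passes_i = ratio > cfg.fold_threshold
        if passes_i and require_normal_silent and normals is not None:
            passes_i = float(normals.loc[tx].max()) < cfg.prevalence_tpm
        prevalence = _prevalence(m, cfg)
        passes_ii = prevalence > cfg.prevalence_fraction
        calls.append(
            SrtCall(
                transcript_id=tx,
                median_tumour=med_m,
                max_normal=med_p,
                prevalence=prevalence,
                passes_i=passes_i,
                passes_ii=passes_ii,
            )
        )
    return calls


def _select_rows(
    matrix: ExpressionMatrix, transcripts: Sequence[str] | None
) -> list[str]:
    if transcripts is None:
        return matrix.transcript_ids
    present = set(matrix.transcript_ids)
    rows = []
    for tx in transcripts:
        if tx not in present:
            warnings.warn(f"transcript {tx} absent from matrix; skipped")
            continue
        rows.append(tx)
    return rows


def calls_to_frame(calls: Sequence[SrtCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "median_tumour": [c.median_tumour for c in calls],
            "max_normal": [c.max_normal for c in calls],
            "prevalence": [c.prevalence for c in calls],
            "passes_i": [c.passes_i for c in calls],
            "passes_ii": [c.passes_ii for c in calls],
            "is_srt": [c.is_srt for c in calls],
        }
    )
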