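"""Differential transcript/gene expression and the DET/DEG decomposition.

Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney U) test —
exact for small tie-free groups, normal approximation with tie and
continuity correction otherwise — with Benjamini-Hochberg correction
across all features tested at a level.  A feature is significant when
|log2 fold change| exceeds 1 and the BH-adjusted p-value (FDR) is below
0.05 (configurable).  Fold changes are computed on group means with a
small pseudocount so zero-expression features stay finite.

Incomplete-splice-match (ISM) transcripts — likely degradation or
incomplete reverse-transcription products — are removed before testing
whenever structural calls are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import StructuralCall
from .io import ExpressionMatrix


@dataclass
class DiffConfig:
    log2_fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    pseudocount: float = 0.01
    paired: bool = False
    exact_max_n: int = 12  # exact rank-sum distribution up to this group size


@dataclass
class DiffResult:
    feature_id: str
    mean_a: float
    mean_b: float
    log2_fc: float
    p_value: float
    fdr: float
    is_significant: bool


def rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups have at most ``exact_max_n`` observations and no
    value is shared between the groups (within-group ties leave the rank
    sum unaffected); otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_cross_ties = not (set(x.tolist()) & set(y.tolist()))
    if no_cross_ties and len(x) <= exact_max_n and len(y) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(diff == 0):
        return 1.0
    res = stats.wilcoxon(diff, alternative="two-sided")
    return float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def differential(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    level: str = "transcript",
    tx2gene: Mapping[str, str] | None = None,
    calls: Sequence[StructuralCall] | None = None,
    cfg: DiffConfig | None = None,
) -> list[DiffResult]:
    """Differential expression between two sample groups.

    ``level="gene"`` requires ``tx2gene``; gene TPM is the sum of member
    transcript TPMs.  When ``calls`` are supplied, ISM-classified
    transcripts are excluded before testing (at either level).
    """
    cfg = cfg or DiffConfig()
    if level not in ("transcript", "gene"):
        raise ValueError(f"level must be 'transcript' or 'gene', got {level!r}")
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    a_samples = matrix.samples_in(group_a)
    b_samples = matrix.samples_in(group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("both groups need at least 2 samples")
    if cfg.paired and len(a_samples) != len(b_samples):
        raise ValueError("paired mode requires equal group sizes")

    values = matrix.values
    if calls is not None:
        ism = {c.transcript_id for c in calls if c.category == "ISM"}
        values = values.loc[[t for t in values.index if t not in ism]]

    if level == "gene":
        if tx2gene is None:
            raise ValueError("gene-level testing requires a transcript-to-gene map")
        missing = [t for t in values.index if t not in tx2gene]
        if missing:
            raise KeyError(f"transcripts missing from tx2gene map: {missing[:5]}")
        genes = pd.Series({t: tx2gene[t] for t in values.index})
        values = values.groupby(genes).sum()

    a = values[a_samples].to_numpy(dtype=float)
    b = values[b_samples].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    eps = cfg.pseudocount
    log2_fc = np.log2((mean_a + eps) / (mean_b + eps))

    p_values = np.empty(len(values))
    for i in range(len(values)):
        if cfg.paired:
            p_values[i] = _paired_p(a[i], b[i])
        else:
            p_values[i] = rank_sum_p(a[i], b[i], cfg.exact_max_n)

    fdr = benjamini_hochberg(p_values)
    results = []
    for i, feature_id in enumerate(values.index):
        significant = (
            abs(log2_fc[i]) > cfg.log2_fc_threshold and fdr[i] < cfg.fdr_threshold
        )
        results.append(
            DiffResult(
                feature_id=str(feature_id),
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2_fc=float(log2_fc[i]),
                p_value=float(p_values[i]),
                fdr=float(fdr[i]),
                is_significant=bool(significant),
            )
        )
    return results


@dataclass
class OverlapDecomposition:
    """Genes split by where their differential signal lives.

    ``det_specific_genes`` carry at least one significant transcript but no
    significant gene-level change; ``deg_specific_genes`` the reverse;
    ``shared_genes`` both.  The three sets are pairwise disjoint.
    """

    det_specific_genes: list[str]
    deg_specific_genes: list[str]
    shared_genes: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "det_specific": len(self.det_specific_genes),
            "deg_specific": len(self.deg_specific_genes),
            "shared": len(self.shared_genes),
        }


def overlap_decomposition(
    det: Sequence[DiffResult],
    deg: Sequence[DiffResult],
    tx2gene: Mapping[str, str],
) -> OverlapDecomposition:
    """Decompose differential signal into DET-specific / DEG-specific / shared."""
    det_genes: set[str] = set()
    for r in det:
        if r.feature_id not in tx2gene:
            raise KeyError(f"transcript {r.feature_id} missing from tx2gene map")
        if r.is_significant:
            det_genes.add(tx2gene[r.feature_id])
    deg_genes = {r.feature_id for r in deg if r.is_significant}
    return OverlapDecomposition(
        det_specific_genes=sorted(det_genes - deg_genes),
        deg_specific_genes=sorted(deg_genes - det_genes),
        shared_genes=sorted(det_genes & deg_genes),
    )


def results_to_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "is_significant": [r.is_significant for r in results],
        }
    )
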