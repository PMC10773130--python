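"""Seeded synthetic dataset generator with known ground truth.

Generates a complete toy study from one seed: a random genome, a
multi-gene/multi-isoform reference annotation, per-sample long-read query
transcript models constructed to have known structural categories,
short-read junction-support tables, and grouped TPM cohorts with planted
tumour-exclusive transcripts, metastasis-specific transcripts and
reciprocal isoform-switch pairs.

Construction of query models per intended category:

* FSM — copy of a reference transcript with jittered terminal-exon ends
  (the junction chain is untouched).
* ISM — contiguous sub-chain of a reference transcript (terminal exons
  additionally shrunk), checked against the chain index so it cannot
  collide with a full reference chain.
* NIC — exon skip within a reference transcript: the new junction links
  two annotated splice sites never combined in one transcript.
* NNC — one splice site shifted >= 12 bp into an intron, guaranteeing
  >= 10 bp distance from every annotated site.
* antisense — a reference chain copied onto the opposite strand.
* intergenic — a model placed >= 10 kb from every gene span.

Expression planting: tumour-exclusive transcripts draw
``baseline x srt_effect`` in tumour samples while every normal sample
draws uniformly from [0, 0.05], so the 10x median-over-max criterion is
satisfiable by construction at the default 50x effect.  Switch genes use
a reciprocal pair (c, 4c) -> (4c, c), which conserves the gene-level sum
exactly in expectation while both transcripts clear the |log2FC| > 1
threshold.  Multiplicative log-normal noise (sigma 0.4 by default) is
applied to every non-planted-zero cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DictGenome,
    ExpressionMatrix,
    JunctionSupportTable,
    write_expression,
    write_fasta,
    write_gtf,
    write_junction_support,
)
from .models import GenomicInterval, ReferenceAnnotation, TranscriptModel

CATEGORY_ORDER = ("FSM", "ISM", "NIC", "NNC", "antisense", "intergenic")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_seqs: int = 2
    seq_length: int = 500_000
    n_genes: int = 30
    transcripts_per_gene: tuple[int, int] = (1, 4)
    exons_per_transcript: tuple[int, int] = (3, 8)
    n_query_transcripts: int = 200
    category_weights: dict = field(
        default_factory=lambda: {
            "FSM": 0.30,
            "ISM": 0.10,
            "NIC": 0.20,
            "NNC": 0.20,
            "antisense": 0.10,
            "intergenic": 0.10,
        }
    )
    n_isoseq_samples: int = 4
    n_tumour: int = 10
    n_normal: int = 10
    n_metastasis: int = 10
    n_primary: int = 10
    srt_fraction: float = 0.03
    srt_effect: float = 50.0
    met_srt_fraction: float = 0.03
    switch_fraction: float = 0.25
    switch_effect: float = 4.0
    polyA_track_fraction: float = 0.3
    polyA_acount_range: tuple[int, int] = (12, 20)
    baseline_log_mean: float = math.log(10.0)
    baseline_log_sigma: float = 1.0
    noise_sigma: float = 0.4
    srt_normal_cap: float = 0.05  # planted SRTs: normal TPM ~ U[0, cap]

    def __post_init__(self) -> None:
        for name in (
            "srt_fraction",
            "met_srt_fraction",
            "switch_fraction",
            "polyA_track_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("transcripts_per_gene", "exons_per_transcript", "polyA_acount_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range is empty or invalid")
        if self.exons_per_transcript[0] < 2:
            raise ValueError("reference transcripts must be multi-exon (>= 2 exons)")
        if self.polyA_acount_range[1] > 20:
            raise ValueError("polyA_acount_range cannot exceed the 20 bp window")


@dataclass
class GroundTruth:
    """Planted truth per transcript, as a tidy frame plus typed accessors."""

    frame: pd.DataFrame  # indexed by transcript_id

    @property
    def query_categories(self) -> dict[str, str]:
        q = self.frame[self.frame["kind"] == "query"]
        return dict(zip(q.index, q["category"]))

    @property
    def srt_ids(self) -> list[str]:
        return sorted(self.frame.index[self.frame["is_srt"]])

    @property
    def met_srt_ids(self) -> list[str]:
        return sorted(self.frame.index[self.frame["is_met_srt"]])

    @property
    def switch_genes(self) -> dict[str, tuple[str, str]]:
        out: dict[str, tuple[str, str]] = {}
        sub = self.frame[self.frame["switch_role"] != "none"]
        for gene_id, grp in sub.groupby("gene_id"):
            up = grp.index[grp["switch_role"] == "up"][0]
            down = grp.index[grp["switch_role"] == "down"][0]
            out[str(gene_id)] = (str(up), str(down))
        return out

    @property
    def downstream_a_counts(self) -> dict[str, int]:
        q = self.frame[self.frame["kind"] == "query"]
        return dict(zip(q.index, q["downstream_a_count"].astype(int)))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    @staticmethod
    def read(path: str | Path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        for col in ("is_srt", "is_met_srt"):
            if frame[col].dtype == object:
                frame[col] = frame[col] == "True"
        return GroundTruth(frame)


@dataclass
class SimulatedDataset:
    """In-memory view of one simulated study."""

    config: SimulationConfig
    genome: DictGenome
    sequences: dict[str, str]
    annotation: ReferenceAnnotation
    reference_models: list[TranscriptModel]
    queries: list[TranscriptModel]  # unique query models
    queries_by_sample: dict[str, list[TranscriptModel]]
    support_by_sample: dict[str, JunctionSupportTable]
    matrix: ExpressionMatrix
    tx2gene: dict[str, str]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation and genome scaffolding


def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    genes_per_seq = math.ceil(cfg.n_genes / cfg.n_seqs)
    pitch = cfg.seq_length // (genes_per_seq + 1)
    reference: list[TranscriptModel] = []
    gene_pools: dict[str, list[GenomicInterval]] = {}
    gene_runs: dict[str, list[tuple[int, int]]] = {}  # gene -> used (start, length)
    spans: dict[str, list[tuple[int, int]]] = {s: [] for s in _seq_names(cfg)}

    gene_index = 0
    for seq_name in _seq_names(cfg):
        for slot in range(genes_per_seq):
            if gene_index >= cfg.n_genes:
                break
            gene_id = f"G{gene_index:03d}"
            anchor = pitch * (slot + 1)
            strand = str(rng.choice(["+", "-"]))
            pool_max = cfg.exons_per_transcript[1]
            pool_size = int(rng.integers(pool_max, pool_max + 3))
            exons: list[GenomicInterval] = []
            pos = anchor
            for _ in range(pool_size):
                length = int(rng.integers(100, 301))
                exons.append(GenomicInterval(seq_name, pos, pos + length, strand))
                pos += length + int(rng.integers(100, 801))
            gene_pools[gene_id] = exons
            spans[seq_name].append((exons[0].start, exons[-1].end))

            n_tx = int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1))
            used: list[tuple[int, int]] = []
            for k in range(n_tx):
                for _ in range(20):
                    lo = cfg.exons_per_transcript[0]
                    hi = min(cfg.exons_per_transcript[1], pool_size)
                    length = int(rng.integers(lo, hi + 1))
                    start = int(rng.integers(0, pool_size - length + 1))
                    if (start, length) not in used:
                        used.append((start, length))
                        reference.append(
                            TranscriptModel(
                                transcript_id=f"{gene_id}.T{len(used)}",
                                exons=tuple(exons[start : start + length]),
                                gene_id=gene_id,
                            )
                        )
                        break
            gene_runs[gene_id] = used
            gene_index += 1

    annotation = ReferenceAnnotation(reference)
    return reference, annotation, gene_pools, gene_runs, spans


def _seq_names(cfg: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_seqs)]


def _intergenic_anchors(
    cfg: SimulationConfig, spans: Mapping[str, list[tuple[int, int]]]
) -> list[tuple[str, int]]:
    """Positions >= 10 kb from every gene span, spaced 3 kb apart."""
    margin = 10_000
    anchors: list[tuple[str, int]] = []
    for seq_name in _seq_names(cfg):
        seq_spans = sorted(spans[seq_name])
        edges = [(1_000, 1_000)] + seq_spans + [
            (cfg.seq_length - 1_000, cfg.seq_length - 1_000)
        ]
        for (_, prev_end), (next_start, _) in zip(edges, edges[1:]):
            lo = prev_end + margin
            hi = next_start - margin - 3_000
            pos = lo
            while pos <= hi:
                anchors.append((seq_name, pos))
                pos += 3_000
    return anchors


# ---------------------------------------------------------------------------
# query construction per intended category


def _category_counts(cfg: SimulationConfig) -> dict[str, int]:
    weights = cfg.category_weights
    total = sum(weights.values())
    raw = {c: cfg.n_query_transcripts * weights.get(c, 0.0) / total for c in CATEGORY_ORDER}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    remainder = cfg.n_query_transcripts - sum(counts.values())
    by_frac = sorted(CATEGORY_ORDER, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def _jitter_ends(
    exons: list[GenomicInterval], rng: np.random.Generator, extend: bool
) -> list[GenomicInterval]:
    first, last = exons[0], exons[-1]
    if extend:
        d_start = -int(rng.integers(0, 21))
        d_end = int(rng.integers(0, 21))
    else:
        d_start = int(rng.integers(0, 31))
        d_end = -int(rng.integers(0, 31))
    exons = list(exons)
    exons[0] = GenomicInterval(
        first.seq_name, max(1, first.start + d_start), first.end, first.strand
    )
    exons[-1] = GenomicInterval(
        last.seq_name, last.start, last.end + d_end, last.strand
    )
    return exons


def _make_queries(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    reference: Sequence[TranscriptModel],
    annotation: ReferenceAnnotation,
    gene_pools: Mapping[str, list[GenomicInterval]],
    gene_runs: Mapping[str, list[tuple[int, int]]],
    spans: Mapping[str, list[tuple[int, int]]],
) -> tuple[list[TranscriptModel], dict[str, str]]:
    counts = _category_counts(cfg)
    anchors = _intergenic_anchors(cfg, spans)
    rng.shuffle(anchors)
    anchor_iter = iter(anchors)
    ref_multi4 = [t for t in reference if len(t.exons) >= 4]

    queries: list[TranscriptModel] = []
    categories: dict[str, str] = {}
    qi = 0
    for category in CATEGORY_ORDER:
        for _ in range(counts[category]):
            qid = f"Q{qi:04d}"
            qi += 1
            model = None
            for _attempt in range(100):
                if category == "FSM":
                    src = reference[int(rng.integers(0, len(reference)))]
                    exons = _jitter_ends(list(src.exons), rng, extend=True)
                    model = TranscriptModel(qid, tuple(exons), gene_id=src.gene_id)
                elif category == "ISM":
                    src = reference[int(rng.integers(0, len(reference)))]
                    n = len(src.exons)
                    if n < 3:
                        continue
                    drop_left = int(rng.integers(0, n - 1))
                    max_right = n - drop_left - 2
                    lo = 1 if drop_left == 0 else 0
                    if max_right < lo:
                        continue
                    drop_right = int(rng.integers(lo, max_right + 1))
                    kept = list(src.exons[drop_left : n - drop_right])
                    if len(kept) < 2:
                        continue
                    exons = _jitter_ends(kept, rng, extend=False)
                    cand = TranscriptModel(qid, tuple(exons), gene_id=src.gene_id)
                    if cand.chain_key() in annotation.chain_index:
                        continue  # would be a full-splice match to a shorter isoform
                    model = cand
                elif category == "NIC":
                    if not ref_multi4:
                        raise ValueError("NIC queries need a reference transcript with >= 4 exons")
                    src = ref_multi4[int(rng.integers(0, len(ref_multi4)))]
                    skip = int(rng.integers(1, len(src.exons) - 1))
                    exons = [e for i, e in enumerate(src.exons) if i != skip]
                    cand = TranscriptModel(qid, tuple(exons), gene_id=src.gene_id)
                    sites = {
                        s
                        for j in cand.junction_chain()
                        for s in j.sites()
                    }
                    if cand.chain_key() in annotation.chain_index:
                        continue
                    if not sites <= annotation.splice_site_index:
                        continue
                    model = cand
                elif category == "NNC":
                    src = reference[int(rng.integers(0, len(reference)))]
                    j_idx = int(rng.integers(0, len(src.exons) - 1))
                    donor_exon = src.exons[j_idx]
                    intron_len = src.exons[j_idx + 1].start - donor_exon.end
                    if intron_len < 30:
                        continue
                    delta = int(rng.integers(12, min(30, intron_len - 12) + 1))
                    new_end = donor_exon.end + delta
                    if _near_any_site(annotation, src.seq_name, new_end, 10):
                        continue
                    exons = list(src.exons)
                    exons[j_idx] = GenomicInterval(
                        donor_exon.seq_name, donor_exon.start, new_end, donor_exon.strand
                    )
                    model = TranscriptModel(qid, tuple(exons), gene_id=src.gene_id)
                elif category == "antisense":
                    src = reference[int(rng.integers(0, len(reference)))]
                    flipped = "-" if src.strand == "+" else "+"
                    exons = tuple(
                        GenomicInterval(e.seq_name, e.start, e.end, flipped)
                        for e in src.exons
                    )
                    model = TranscriptModel(qid, exons, gene_id=None)
                else:  # intergenic
                    try:
                        seq_name, anchor = next(anchor_iter)
                    except StopIteration as exc:
                        raise ValueError("ran out of intergenic placements") from exc
                    strand = str(rng.choice(["+", "-"]))
                    n_ex = int(rng.integers(1, 4))
                    exons = []
                    pos = anchor
                    for _ in range(n_ex):
                        length = int(rng.integers(200, 401))
                        exons.append(GenomicInterval(seq_name, pos, pos + length, strand))
                        pos += length + int(rng.integers(200, 501))
                    model = TranscriptModel(qid, tuple(exons), gene_id=None)
                if model is not None:
                    break
            if model is None:
                raise RuntimeError(f"could not construct a {category} query")
            queries.append(model)
            categories[qid] = category
    return queries, categories


def _near_any_site(
    annotation: ReferenceAnnotation, seq_name: str, pos: int, min_dist: int
) -> bool:
    for (s, _strand, p, _role) in annotation.splice_site_index:
        if s == seq_name and abs(p - pos) < min_dist:
            return True
    return False


# ---------------------------------------------------------------------------
# expression cohorts


def _sample_names(cfg: SimulationConfig) -> tuple[list[str], pd.Series]:
    names: list[str] = []
    groups: list[str] = []
    for prefix, group, n in (
        ("T", "tumour", cfg.n_tumour),
        ("N", "normal", cfg.n_normal),
        ("M", "metastasis", cfg.n_metastasis),
        ("P", "primary", cfg.n_primary),
    ):
        for i in range(n):
            names.append(f"{prefix}{i + 1:02d}")
            groups.append(group)
    return names, pd.Series(groups, index=names)


def _build_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    row_ids: list[str],
    tx2gene: Mapping[str, str],
    multi_isoform_genes: list[str],
    gene_members: Mapping[str, list[str]],
) -> tuple[ExpressionMatrix, set[str], set[str], dict[str, tuple[str, str]]]:
    samples, groups = _sample_names(cfg)
    n_rows = len(row_ids)
    idx = {s: i for i, s in enumerate(samples)}
    group_cols = {
        g: [idx[s] for s in samples if groups[s] == g]
        for g in ("tumour", "normal", "metastasis", "primary")
    }

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, size=n_rows)

    # choose switch genes first, then plant SRTs outside them
    n_switch = int(round(cfg.switch_fraction * len(multi_isoform_genes)))
    switch_gene_ids = sorted(
        rng.choice(multi_isoform_genes, size=n_switch, replace=False)
    ) if n_switch else []
    switch_pairs: dict[str, tuple[str, str]] = {}
    row_pos = {t: i for i, t in enumerate(row_ids)}
    for gene_id in switch_gene_ids:
        members = sorted(gene_members[gene_id])
        pick = rng.choice(len(members), size=2, replace=False)
        up_tx, down_tx = members[int(pick[0])], members[int(pick[1])]
        switch_pairs[gene_id] = (up_tx, down_tx)

    switch_rows = {t for pair in switch_pairs.values() for t in pair}
    eligible = [
        t
        for t in row_ids
        if tx2gene[t] not in switch_pairs and t not in switch_rows
    ]
    n_srt = int(round(cfg.srt_fraction * n_rows))
    n_met = int(round(cfg.met_srt_fraction * n_rows))
    planted = rng.choice(len(eligible), size=min(n_srt + n_met, len(eligible)), replace=False)
    srt_ids = {eligible[int(i)] for i in planted[:n_srt]}
    met_ids = {eligible[int(i)] for i in planted[n_srt : n_srt + n_met]}

    # per-cell means, then multiplicative log-normal noise
    means = np.tile(baseline[:, None], (1, len(samples)))
    for tx, pos in row_pos.items():
        if tx in srt_ids:
            means[pos, group_cols["tumour"]] = baseline[pos] * cfg.srt_effect
        elif tx in met_ids:
            means[pos, group_cols["metastasis"]] = baseline[pos] * cfg.srt_effect
    for gene_id, (up_tx, down_tx) in sorted(switch_pairs.items()):
        c = float(rng.lognormal(math.log(5.0), 0.5))
        e = cfg.switch_effect
        up_pos, down_pos = row_pos[up_tx], row_pos[down_tx]
        means[up_pos, :] = c
        means[down_pos, :] = e * c
        means[up_pos, group_cols["tumour"]] = e * c
        means[down_pos, group_cols["tumour"]] = c

    noise = rng.lognormal(0.0, cfg.noise_sigma, size=means.shape)
    values = means * noise
    # planted-zero cells overwrite the noise draw
    for tx in sorted(srt_ids):
        values[row_pos[tx], group_cols["normal"]] = rng.uniform(
            0.0, cfg.srt_normal_cap, size=len(group_cols["normal"])
        )
    for tx in sorted(met_ids):
        values[row_pos[tx], group_cols["primary"]] = rng.uniform(
            0.0, cfg.srt_normal_cap, size=len(group_cols["primary"])
        )

    frame = pd.DataFrame(np.round(values, 6), index=row_ids, columns=samples)
    matrix = ExpressionMatrix(values=frame, groups=groups)
    return matrix, srt_ids, met_ids, switch_pairs


def null_expression_matrix(
    n_transcripts: int,
    n_a: int,
    n_b: int,
    seed: int,
    group_a: str = "tumour",
    group_b: str = "normal",
    baseline_log_mean: float = math.log(10.0),
    baseline_log_sigma: float = 1.0,
    noise_sigma: float = 0.4,
) -> ExpressionMatrix:
    """Two-group TPM matrix with no planted effects (for null calibration)."""
    rng = np.random.default_rng(seed)
    samples = [f"A{i + 1:03d}" for i in range(n_a)] + [
        f"B{i + 1:03d}" for i in range(n_b)
    ]
    groups = pd.Series([group_a] * n_a + [group_b] * n_b, index=samples)
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sigma, size=n_transcripts)
    noise = rng.lognormal(0.0, noise_sigma, size=(n_transcripts, n_a + n_b))
    values = pd.DataFrame(
        baseline[:, None] * noise,
        index=[f"TX{i + 1:05d}" for i in range(n_transcripts)],
        columns=samples,
    )
    return ExpressionMatrix(values=values, groups=groups)


# ---------------------------------------------------------------------------
# top-level generator


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Build the full synthetic study in memory (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    reference, annotation, gene_pools, gene_runs, spans = _build_annotation(cfg, rng)
    queries, categories = _make_queries(
        cfg, rng, reference, annotation, gene_pools, gene_runs, spans
    )

    # genome: uniform random ACGT, then planted adenine tracts downstream of
    # selected query 3' ends
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    sequences_arr = {
        seq: rng.choice(alphabet, size=cfg.seq_length).copy()
        for seq in _seq_names(cfg)
    }
    planned_acount: dict[str, int] = {}
    for q in queries:
        if rng.random() < cfg.polyA_track_fraction:
            acount = int(
                rng.integers(cfg.polyA_acount_range[0], cfg.polyA_acount_range[1] + 1)
            )
            planned_acount[q.transcript_id] = acount
            arr = sequences_arr[q.seq_name]
            if q.strand == "+":
                arr[q.end : q.end + acount] = b"A"
            else:
                arr[q.start - acount : q.start] = b"T"
    sequences = {
        seq: arr.tobytes().decode("ascii") for seq, arr in sequences_arr.items()
    }
    genome = DictGenome(sequences)

    # actual downstream adenine counts, measured from the final genome
    from .filters import downstream_a_count

    a_counts = {
        q.transcript_id: downstream_a_count(q, genome, 20)[0] for q in queries
    }

    # distribute queries over long-read samples
    isoseq_samples = [f"ISO{i + 1:02d}" for i in range(cfg.n_isoseq_samples)]
    base_probs = [0.2, 0.35, 0.25, 0.2]
    if cfg.n_isoseq_samples <= 4:
        occ_probs = np.array(base_probs[: cfg.n_isoseq_samples])
    else:
        occ_probs = np.array(base_probs + [0.1] * (cfg.n_isoseq_samples - 4))
    occ_probs = occ_probs / occ_probs.sum()
    queries_by_sample: dict[str, list[TranscriptModel]] = {s: [] for s in isoseq_samples}
    occurrences: dict[str, list[str]] = {}
    for q in queries:
        k = int(rng.choice(np.arange(1, len(isoseq_samples) + 1), p=occ_probs))
        chosen = sorted(rng.choice(isoseq_samples, size=k, replace=False))
        occurrences[q.transcript_id] = list(chosen)
        for s in chosen:
            queries_by_sample[s].append(
                TranscriptModel(
                    q.transcript_id, q.exons, gene_id=q.gene_id, source_sample=s
                )
            )

    # short-read junction support per sample
    support_by_sample: dict[str, JunctionSupportTable] = {}
    for s in isoseq_samples:
        table = JunctionSupportTable()
        seen = set()
        for m in queries_by_sample[s]:
            for j in m.junction_chain():
                key = (j.seq_name, j.donor, j.acceptor, j.strand)
                if key in seen:
                    continue
                seen.add(key)
                table.add(*key, count=1 + int(rng.poisson(20)))
        support_by_sample[s] = table

    # transcript -> gene map over the expression universe
    tx2gene: dict[str, str] = {t.transcript_id: t.gene_id for t in reference}
    for q in queries:
        if categories[q.transcript_id] in ("antisense", "intergenic"):
            tx2gene[q.transcript_id] = f"NOVELG_{q.transcript_id}"
        else:
            tx2gene[q.transcript_id] = q.gene_id

    gene_members: dict[str, list[str]] = {}
    for tx, gene in tx2gene.items():
        gene_members.setdefault(gene, []).append(tx)
    multi_isoform_genes = sorted(
        g
        for g in annotation.genes
        if len(annotation.genes[g].transcript_ids) >= 2
    )
    ref_gene_members = {
        g: list(annotation.genes[g].transcript_ids) for g in annotation.genes
    }

    row_ids = sorted(t.transcript_id for t in reference) + sorted(
        q.transcript_id for q in queries
    )
    matrix, srt_ids, met_ids, switch_pairs = _build_expression(
        cfg, rng, row_ids, tx2gene, multi_isoform_genes, ref_gene_members
    )

    rows = []
    for tx in row_ids:
        is_query = tx in categories
        role = "none"
        for gene_id, (up, down) in switch_pairs.items():
            if tx == up:
                role = "up"
            elif tx == down:
                role = "down"
        rows.append(
            {
                "transcript_id": tx,
                "kind": "query" if is_query else "reference",
                "category": categories.get(tx, "reference"),
                "gene_id": tx2gene[tx],
                "isoseq_samples": ",".join(occurrences.get(tx, [])),
                "n_isoseq_samples": len(occurrences.get(tx, [])),
                "planned_polya_a": planned_acount.get(tx, 0),
                "downstream_a_count": a_counts.get(tx, -1),
                "is_srt": tx in srt_ids,
                "is_met_srt": tx in met_ids,
                "switch_role": role,
            }
        )
    truth = GroundTruth(pd.DataFrame(rows).set_index("transcript_id"))

    return SimulatedDataset(
        config=cfg,
        genome=genome,
        sequences=sequences,
        annotation=annotation,
        reference_models=reference,
        queries=queries,
        queries_by_sample=queries_by_sample,
        support_by_sample=support_by_sample,
        matrix=matrix,
        tx2gene=tx2gene,
        truth=truth,
    )


def simulate(cfg: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Generate the dataset and write every artifact to ``out_dir``.

    Writes genome.fa, reference.gtf, per-sample isoseq_*.gtf and
    junctions_*.tsv, expression.tsv, groups.tsv, tx2gene.tsv and
    ground_truth.tsv.  Re-running with the same config produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)

    write_fasta(ds.sequences, out / "genome.fa")
    write_gtf(ds.reference_models, out / "reference.gtf")
    for sample, models in sorted(ds.queries_by_sample.items()):
        write_gtf(models, out / f"isoseq_{sample}.gtf")
        write_junction_support(ds.support_by_sample[sample], out / f"junctions_{sample}.tsv")
    write_expression(ds.matrix, out / "expression.tsv", out / "groups.tsv")
    with open(out / "tx2gene.tsv", "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx in sorted(ds.tx2gene):
            fh.write(f"{tx}\t{ds.tx2gene[tx]}\n")
    ds.truth.write(out / "ground_truth.tsv")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return ds.truth
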