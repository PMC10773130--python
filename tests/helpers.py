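"""Shared test utilities: model builders, brute-force oracles and random
instance generators kept deliberately independent of the library's own
algorithms."""

from __future__ import annotations

from itertools import combinations

import numpy as np

from isocall.io import DictGenome
from isocall.models import (
    GenomicInterval,
    JunctionSupportTable,
    ReferenceAnnotation,
    TranscriptModel,
)


def make_tx(tid, seq, strand, blocks, gene=None, sample=None) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(seq, s, e, strand) for s, e in blocks),
        gene_id=gene,
        source_sample=sample,
    )


# ---------------------------------------------------------------------------
# brute-force structural-category oracle: enumerate all reference chains and
# all their contiguous sub-chains, apply the category definitions literally


def _chain(t: TranscriptModel):
    return tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))


def _gene_spans(ref_models):
    spans = {}
    for t in ref_models:
        g = spans.get(t.gene_id)
        if g is None:
            spans[t.gene_id] = [t.seq_name, t.strand, t.start, t.end]
        else:
            g[2] = min(g[2], t.start)
            g[3] = max(g[3], t.end)
    return spans


def oracle_classify(query: TranscriptModel, ref_models) -> str:
    spans = _gene_spans(ref_models)
    same = [
        t
        for t in ref_models
        if t.seq_name == query.seq_name and t.strand == query.strand
    ]

    def overlaps_gene(strand):
        return any(
            seq == query.seq_name
            and s == strand
            and st < query.end
            and query.start < en
            for (seq, s, st, en) in spans.values()
        )

    opposite = "-" if query.strand == "+" else "+"

    if len(query.exons) == 1:
        iv = query.exons[0]
        if any(
            len(t.exons) == 1 and t.start == iv.start and t.end == iv.end
            for t in same
        ):
            return "FSM"
        for t in same:
            for e in t.exons:
                if e.start <= iv.start and iv.end <= e.end:
                    return "ISM"
        if overlaps_gene(query.strand):
            return "other_genic"
        if overlaps_gene(opposite):
            return "antisense"
        return "intergenic"

    qc = _chain(query)
    ref_chains = {_chain(t) for t in same if len(t.exons) > 1}
    if qc in ref_chains:
        return "FSM"
    subchains = set()
    for c in ref_chains:
        for i in range(len(c)):
            for j in range(i + 1, len(c) + 1):
                subchains.add(c[i:j])
    if qc in subchains:
        return "ISM"

    def sites_of(chain, strand):
        out = set()
        for (d, a) in chain:
            if strand == "+":
                out.add((d, "donor"))
                out.add((a, "acceptor"))
            else:
                out.add((d, "acceptor"))
                out.add((a, "donor"))
        return out

    known = set()
    for t in same:
        known |= sites_of(_chain(t), t.strand)
    if sites_of(qc, query.strand) <= known:
        return "NIC"
    if overlaps_gene(query.strand):
        return "NNC"
    if overlaps_gene(opposite):
        return "antisense"
    return "intergenic"


def random_reference(rng: np.random.Generator):
    """Small random annotation: shared per-gene exon pools, arbitrary
    (possibly non-contiguous) exon subsets as transcripts."""
    ref = []
    n_genes = int(rng.integers(1, 11))
    for gi in range(n_genes):
        seq = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(100, 50_001))
        n_ex = int(rng.integers(2, 9))
        pool = []
        for _ in range(n_ex):
            ln = int(rng.integers(20, 101))
            pool.append((pos, pos + ln))
            pos += ln + int(rng.integers(20, 101))
        n_tx = int(rng.integers(1, 6))
        for k in range(n_tx):
            size = int(rng.integers(1, min(6, n_ex) + 1))
            idx = sorted(rng.choice(n_ex, size=size, replace=False))
            exons = tuple(
                GenomicInterval(seq, pool[i][0], pool[i][1], strand) for i in idx
            )
            ref.append(TranscriptModel(f"G{gi}.T{k}", exons, gene_id=f"G{gi}"))
    return ref


def random_query(rng: np.random.Generator, ref, qid: str) -> TranscriptModel:
    """A random query model derived from (or unrelated to) the reference."""
    for _ in range(200):
        src = ref[int(rng.integers(0, len(ref)))]
        mode = int(rng.integers(0, 6))
        try:
            if mode == 0:  # copy with jittered terminal ends
                exons = list(src.exons)
                first, last = exons[0], exons[-1]
                exons[0] = GenomicInterval(
                    first.seq_name,
                    max(0, first.start + int(rng.integers(-10, 11))),
                    first.end,
                    first.strand,
                )
                exons[-1] = GenomicInterval(
                    last.seq_name,
                    exons[-1].start if len(exons) > 1 else exons[0].start,
                    last.end + int(rng.integers(-10, 11)),
                    last.strand,
                )
                return TranscriptModel(qid, tuple(exons))
            if mode == 1:  # exon subset (possibly non-contiguous)
                n = len(src.exons)
                size = int(rng.integers(1, n + 1))
                idx = sorted(rng.choice(n, size=size, replace=False))
                return TranscriptModel(qid, tuple(src.exons[i] for i in idx))
            if mode == 2:  # perturb one internal boundary
                exons = list(src.exons)
                i = int(rng.integers(0, len(exons)))
                e = exons[i]
                delta = int(rng.integers(1, 26)) * (1 if rng.random() < 0.5 else -1)
                if rng.random() < 0.5:
                    exons[i] = GenomicInterval(e.seq_name, e.start + delta, e.end, e.strand)
                else:
                    exons[i] = GenomicInterval(e.seq_name, e.start, e.end + delta, e.strand)
                return TranscriptModel(qid, tuple(exons))
            if mode == 3:  # strand flip
                flipped = "-" if src.strand == "+" else "+"
                return TranscriptModel(
                    qid,
                    tuple(
                        GenomicInterval(e.seq_name, e.start, e.end, flipped)
                        for e in src.exons
                    ),
                )
            if mode == 4:  # distant model
                seq = f"chr{int(rng.integers(1, 3))}"
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(200_000, 400_000))
                n_ex = int(rng.integers(1, 4))
                exons = []
                for _ in range(n_ex):
                    ln = int(rng.integers(30, 120))
                    exons.append(GenomicInterval(seq, pos, pos + ln, strand))
                    pos += ln + int(rng.integers(30, 120))
                return TranscriptModel(qid, tuple(exons))
            # mode 5: mono-exon near the source gene
            e = src.exons[int(rng.integers(0, len(src.exons)))]
            offset = int(rng.integers(-60, 61))
            start = max(0, e.start + offset)
            ln = int(rng.integers(10, 1 + max(11, e.end - e.start + 40)))
            strand = src.strand if rng.random() < 0.8 else (
                "-" if src.strand == "+" else "+"
            )
            return TranscriptModel(
                qid, (GenomicInterval(e.seq_name, start, start + ln, strand),)
            )
        except ValueError:
            continue
    raise RuntimeError("could not build a random query")


# ---------------------------------------------------------------------------
# literal Benjamini-Hochberg step-up


def bh_literal(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# exact rank-sum p by full enumeration of label assignments


def _u_statistic(x, y) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p: P(|U - mu| >= |U_obs - mu|) over all
    C(n1+n2, n1) equally likely group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    d_obs = abs(_u_statistic(x, y) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(_u_statistic(xs, ys) - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# random inputs for filter-cascade property tests

def random_cascade_inputs(rng):
    """Small random per-sample models + reference + support + genome."""
    n_ref = int(rng.integers(1, 4))
    ref_models = []
    pos = 1000
    for i in range(n_ref):
        blocks = []
        for _ in range(int(rng.integers(2, 5))):
            ln = int(rng.integers(50, 150))
            blocks.append((pos, pos + ln))
            pos += ln + int(rng.integers(50, 150))
        ref_models.append(make_tx(f"R{i}", "chr1", "+", blocks, gene=f"G{i}"))
        pos += 2000
    ref = ReferenceAnnotation(ref_models)
    genome_len = pos + 5000
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=genome_len)
    genome = DictGenome({"chr1": bases.tobytes().decode()})

    per_sample = {}
    support = JunctionSupportTable()
    for s in ("S1", "S2", "S3"):
        models = []
        for k in range(int(rng.integers(1, 5))):
            src = ref_models[int(rng.integers(0, n_ref))]
            if rng.random() < 0.5 and len(src.exons) >= 3:
                exons = src.exons[1:]  # ISM-like
            else:
                exons = src.exons
            models.append(
                make_tx(f"{s}_q{k}", "chr1", "+", [(e.start, e.end) for e in exons])
            )
            for j_ in models[-1].junction_chain():
                if rng.random() < 0.8:
                    support.add(
                        j_.seq_name, j_.donor, j_.acceptor, j_.strand,
                        int(rng.integers(1, 6)),
                    )
        per_sample[s] = models
    return per_sample, ref, support, genome
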