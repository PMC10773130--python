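"""Core domain types for transcript-model analysis.

All coordinates are 0-based, half-open genomic intervals; GTF I/O converts at
the boundary.  A transcript model is an ordered block of exons on one sequence
and strand; its identity for structural comparison is the *junction chain* —
the ordered list of intron intervals between adjacent exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open interval on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class Junction:
    """An intron as a half-open interval [donor, acceptor) on the genome.

    ``donor`` is the first intronic base and ``acceptor`` one past the last —
    genomic-left/right edges, irrespective of strand.  Biological donor and
    acceptor roles are strand-dependent and exposed via :meth:`sites`.
    """

    seq_name: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.donor < self.acceptor):
            raise ValueError(f"invalid junction ({self.donor}, {self.acceptor})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def sites(self) -> tuple[tuple[str, str, int, str], tuple[str, str, int, str]]:
        """The two splice sites as (seq, strand, position, role) tuples."""
        if self.strand == "+":
            left_role, right_role = "donor", "acceptor"
        else:
            left_role, right_role = "acceptor", "donor"
        return (
            (self.seq_name, self.strand, self.donor, left_role),
            (self.seq_name, self.strand, self.acceptor, right_role),
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exon-block transcript model.

    Exons are sorted by start, pairwise non-overlapping and separated by at
    least one intronic base; all share one sequence name and strand.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str | None = None
    source_sample: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        seqs = {e.seq_name for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqs) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple sequences/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and separated "
                    f"by >= 1 bp (got [{a.start},{a.end}) then [{b.start},{b.end}))"
                )

    @property
    def seq_name(self) -> str:
        return self.exons[0].seq_name

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    def junction_chain(self) -> tuple[Junction, ...]:
        return junction_chain(self)

    def chain_key(self) -> tuple[str, str, tuple[tuple[int, int], ...]]:
        """Hashable identity of the junction chain (seq, strand, intron pairs)."""
        return (
            self.seq_name,
            self.strand,
            tuple((j.donor, j.acceptor) for j in self.junction_chain()),
        )

    def tts(self) -> int:
        """Genomic position of the transcription termination site (3' end)."""
        return self.end if self.strand == "+" else self.start


def junction_chain(t: TranscriptModel) -> tuple[Junction, ...]:
    """Ordered intron intervals between adjacent exons (empty for mono-exon)."""
    return tuple(
        Junction(t.seq_name, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    )


@dataclass
class GeneRecord:
    gene_id: str
    seq_name: str
    strand: str
    start: int
    end: int
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_name, self.start, self.end, self.strand)


class ReferenceAnnotation:
    """Indexed view of a reference transcriptome.

    Builds, from a set of reference transcript models, the indexes the
    structural classifier needs: splice sites (with donor/acceptor role),
    junctions, exact junction-chain lookup and a gene-span interval index.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneRecord] = {}
        self.splice_site_index: set[tuple[str, str, int, str]] = set()
        self.junction_index: set[Junction] = set()
        self.chain_index: dict[tuple, list[str]] = {}
        self._tx_by_junction: dict[Junction, list[str]] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._mono_exon_index: dict[tuple[str, str, int, int], list[str]] = {}

        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate reference transcript {t.transcript_id}")
            if t.gene_id is None:
                raise ValueError(
                    f"reference transcript {t.transcript_id} lacks a gene_id"
                )
            self.transcripts[t.transcript_id] = t
            gene = self.genes.get(t.gene_id)
            if gene is None:
                gene = GeneRecord(t.gene_id, t.seq_name, t.strand, t.start, t.end)
                self.genes[t.gene_id] = gene
            else:
                if gene.strand != t.strand or gene.seq_name != t.seq_name:
                    raise ValueError(
                        f"gene {t.gene_id}: transcripts on mixed strands/sequences"
                    )
                gene.start = min(gene.start, t.start)
                gene.end = max(gene.end, t.end)
            gene.transcript_ids.append(t.transcript_id)

            chain = t.junction_chain()
            for j in chain:
                self.junction_index.add(j)
                self.splice_site_index.update(j.sites())
                self._tx_by_junction.setdefault(j, []).append(t.transcript_id)
            self.chain_index.setdefault(t.chain_key(), []).append(t.transcript_id)
            if t.is_mono_exon:
                key = (t.seq_name, t.strand, t.start, t.end)
                self._mono_exon_index.setdefault(key, []).append(t.transcript_id)

        for gene in self.genes.values():
            tree = self._gene_trees.setdefault(gene.seq_name, IntervalTree())
            tree[gene.start : gene.end] = gene.gene_id
        for ids in self.chain_index.values():
            ids.sort()
        for ids in self._tx_by_junction.values():
            ids.sort()
        for ids in self._mono_exon_index.values():
            ids.sort()

    def overlapping_genes(
        self, seq_name: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneRecord]:
        """Genes whose span overlaps [start, end), optionally strand-filtered."""
        tree = self._gene_trees.get(seq_name)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: g.gene_id)

    def chain_matches(self, t: TranscriptModel) -> list[str]:
        """Reference transcript ids whose chain equals the query's exactly."""
        return list(self.chain_index.get(t.chain_key(), []))

    def transcripts_containing_junction(self, j: Junction) -> list[str]:
        return list(self._tx_by_junction.get(j, []))

    def mono_exon_matches(self, t: TranscriptModel) -> list[str]:
        key = (t.seq_name, t.strand, t.start, t.end)
        return list(self._mono_exon_index.get(key, []))

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[i] for i in self.genes[gene_id].transcript_ids]

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())


class JunctionSupportTable:
    """Short-read support counts per splice junction.

    Keys are intron intervals; a strand of ``.`` in the input matches either
    strand at lookup time.  Absent junctions have count 0.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, int, int, str], int] = {}

    def add(self, seq_name: str, donor: int, acceptor: int, strand: str, count: int) -> None:
        if count < 0:
            raise ValueError(
                f"negative junction support for ({seq_name}, {donor}, {acceptor})"
            )
        if strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {strand!r} in junction support")
        key = (seq_name, donor, acceptor, strand)
        self._counts[key] = self._counts.get(key, 0) + count

    def get(self, junction: Junction) -> int:
        base = (junction.seq_name, junction.donor, junction.acceptor)
        return self._counts.get(base + (junction.strand,), 0) + self._counts.get(
            base + (".",), 0
        )

    def update(self, other: "JunctionSupportTable") -> None:
        for (seq, donor, acceptor, strand), count in other._counts.items():
            self.add(seq, donor, acceptor, strand, count)

    def __len__(self) -> int:
        return len(self._counts)

    def items(self):
        return self._counts.items()
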