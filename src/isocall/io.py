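"""Readers and writers for the formats the pipeline touches.

GTF (1-based, closed intervals) is converted to the internal 0-based
half-open convention at the boundary.  Junction-support tables use the
common aligner dialect: five tab-separated columns
``seq_name  intron_start(1-based)  intron_end(1-based, inclusive)  strand  count``.
Expression matrices are plain TSV (rows = transcripts, columns = samples)
with a separate two-column sample-to-group map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .models import (
    GenomicInterval,
    JunctionSupportTable,
    ReferenceAnnotation,
    TranscriptModel,
)


class GtfParseError(ValueError):
    """A malformed GTF line; the message names the file and line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, kind: str = "query"):
    """Read transcript models from a GTF file.

    Parameters
    ----------
    path:
        GTF file with ``exon`` features carrying a ``transcript_id``
        attribute (and ``gene_id`` when ``kind="reference"``).
    kind:
        ``"reference"`` returns a fully indexed :class:`ReferenceAnnotation`;
        ``"query"`` returns a list of :class:`TranscriptModel`.
    """
    if kind not in ("reference", "query"):
        raise ValueError(f"kind must be 'reference' or 'query', got {kind!r}")
    path = Path(path)
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_by_tx: dict[str, str | None] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            feature = fields[2]
            if feature != "exon":
                continue
            try:
                start_1 = int(fields[3])
                end_1 = int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[6]
            if strand not in ("+", "-"):
                # unknown strand is rejected, not guessed: classification is
                # strand-dependent
                raise GtfParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            attrs = _parse_attributes(fields[8])
            tx_id = attrs.get("transcript_id")
            if not tx_id:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks a transcript_id attribute"
                )
            gene_id = attrs.get("gene_id") or None
            if kind == "reference" and gene_id is None:
                raise GtfParseError(
                    f"{path}:{lineno}: reference exon lacks a gene_id attribute"
                )
            if start_1 < 1 or end_1 < start_1:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinates {start_1}..{end_1}"
                )
            interval = GenomicInterval(fields[0], start_1 - 1, end_1, strand)
            if tx_id not in exons_by_tx:
                exons_by_tx[tx_id] = []
                gene_by_tx[tx_id] = gene_id
                order.append(tx_id)
            exons_by_tx[tx_id].append(interval)

    models = []
    for tx_id in order:
        exons = sorted(exons_by_tx[tx_id], key=lambda e: (e.start, e.end))
        models.append(
            TranscriptModel(transcript_id=tx_id, exons=tuple(exons), gene_id=gene_by_tx[tx_id])
        )
    if kind == "reference":
        return ReferenceAnnotation(models)
    return models


def write_gtf(
    models: Iterable[TranscriptModel], path: str | Path, source: str = "isocall"
) -> None:
    """Write transcript models as GTF exon (and transcript) lines."""
    with open(path, "w") as fh:
        for t in models:
            attrs = f'transcript_id "{t.transcript_id}";'
            if t.gene_id is not None:
                attrs = f'gene_id "{t.gene_id}"; ' + attrs
            fh.write(
                "\t".join(
                    [
                        t.seq_name,
                        source,
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.seq_name,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_junction_support(paths: Sequence[str | Path]) -> JunctionSupportTable:
    """Read and pool junction read-support tables across files.

    Counts for the same junction are summed; an empty file list yields an
    empty table on which every lookup returns 0.
    """
    table = JunctionSupportTable()
    for path in paths:
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                    )
                seq, start_1, end_1, strand, count = fields
                count = int(count)
                if count < 0:
                    raise ValueError(f"{path}:{lineno}: negative read count")
                donor = int(start_1) - 1  # 1-based inclusive -> 0-based half-open
                acceptor = int(end_1)
                if not (0 <= donor < acceptor):
                    raise ValueError(f"{path}:{lineno}: invalid intron coordinates")
                table.add(seq, donor, acceptor, strand, count)
    return table


def write_junction_support(
    table: JunctionSupportTable, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for (seq, donor, acceptor, strand), count in sorted(table.items()):
            fh.write(f"{seq}\t{donor + 1}\t{acceptor}\t{strand}\t{count}\n")


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM matrix with sample group labels."""

    values: pd.DataFrame
    groups: pd.Series  # index: sample_id, values: group label

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative TPM values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate transcript ids in expression matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(
                f"samples missing from the group map: {sorted(missing)}"
            )
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        samples = self.samples_in(group)
        if not samples:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[samples]


def read_expression(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if groups_df.shape[1] < 2:
        raise ValueError(f"{groups_path}: expected columns sample_id and group")
    groups = pd.Series(
        groups_df.iloc[:, 1].values, index=groups_df.iloc[:, 0].astype(str)
    )
    if groups.index.has_duplicates:
        raise ValueError(f"{groups_path}: duplicate sample ids")
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, groups_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f")
    with open(groups_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in matrix.groups.items():
            fh.write(f"{sample}\t{group}\n")


class GenomeSource:
    """Minimal genome-sequence accessor interface used by the filters."""

    def fetch(self, seq_name: str, start: int, end: int) -> str:
        raise NotImplementedError

    def length(self, seq_name: str) -> int:
        raise NotImplementedError


class FastaGenome(GenomeSource):
    """Genome accessor backed by an indexed FASTA file (pyfaidx)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, seq_name: str, start: int, end: int) -> str:
        return str(self._fasta[seq_name][start:end])

    def length(self, seq_name: str) -> int:
        return len(self._fasta[seq_name])


class DictGenome(GenomeSource):
    """In-memory genome accessor, mainly for simulation and tests."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def fetch(self, seq_name: str, start: int, end: int) -> str:
        return self._seqs[seq_name][start:end]

    def length(self, seq_name: str) -> int:
        return len(self._seqs[seq_name])


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
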