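"""Reading and writing proteomes, essentiality labels, and score tables.

Proteomes are plain protein FASTA; essentiality annotations are two-column
tab-separated tables (gene id, essential flag) in the style of exports from
the DEG / OGEE essentiality repositories; score tables are the predictor's
tab-separated output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "Proteome",
    "LabelTable",
    "ALLOWED_LETTERS",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "write_scores",
    "read_scores",
]

#: The 20 standard amino acids plus the ambiguity letters accepted on input.
ALLOWED_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXU*")

_TRUE_FLAGS = frozenset({"1", "e", "true"})
_FALSE_FLAGS = frozenset({"0", "ne", "false"})


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a gene id, free-text description, amino-acid sequence."""

    gene_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.gene_id!r} has an empty sequence")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            raise ValueError(
                f"record {self.gene_id!r} contains illegal character(s) "
                f"{''.join(sorted(bad))!r}"
            )


@dataclass(frozen=True)
class Proteome:
    """A genome id together with its ordered protein records."""

    genome_id: str
    records: Tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"proteome {self.genome_id!r} has no records")
        seen = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(
                    f"duplicate gene_id {rec.gene_id!r} in proteome "
                    f"{self.genome_id!r}"
                )
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> Tuple[str, ...]:
        return tuple(rec.gene_id for rec in self.records)

    def sequence_of(self, gene_id: str) -> str:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec.sequence
        raise KeyError(gene_id)


@dataclass(frozen=True)
class LabelTable:
    """Per-gene essentiality flags for one genome.

    Genes of the paired proteome that carry no entry are *unlabeled*: they
    are excluded from evaluation and treated as non-essential when the
    genome serves as a reference.
    """

    genome_id: str
    labels: Dict[str, bool] = field(default_factory=dict)

    def is_essential(self, gene_id: str) -> bool:
        """Essentiality for reference use: unlabeled genes count as False."""
        return self.labels.get(gene_id, False)

    @property
    def n_essential(self) -> int:
        return sum(self.labels.values())

    @property
    def n_nonessential(self) -> int:
        return len(self.labels) - self.n_essential


def read_fasta(path: os.PathLike | str, genome_id: str | None = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The header token before the first whitespace becomes the gene id, the
    remainder the description.  Sequences are upper-cased, whitespace is
    removed and one trailing stop symbol ``*`` is stripped.

    Parameters
    ----------
    path:
        FASTA file with ``>`` headers.
    genome_id:
        Identifier for the genome; defaults to the file name stem.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with open(path) as fh:
        text = fh.read()
    # drop blank lines up front; the strict fasta parser rejects a leading one
    stream = StringIO("\n".join(l for l in text.splitlines() if l.strip()))
    records: List[ProteinRecord] = []
    for rec in SeqIO.parse(stream, "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(rec.id, rec.description[len(rec.id):].strip(), seq))
    if not records:
        raise ValueError(f"no records found in {path!s}")
    return Proteome(genome_id, tuple(records))


def write_fasta(path: os.PathLike | str, proteome: Proteome, width: int = 60) -> None:
    """Write a proteome as protein FASTA, wrapping sequences at `width`."""
    with open(path, "w") as fh:
        for rec in proteome:
            header = f">{rec.gene_id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: os.PathLike | str, proteome: Proteome) -> LabelTable:
    """Read a two-column tab-separated essentiality table for `proteome`.

    Accepted flags (case-insensitive): ``1/0``, ``E/NE``, ``true/false``.
    Lines starting with ``#`` and blank lines are ignored.  Every gene id
    must occur in the proteome; anything else is an error, never a warning.
    """
    known = set(proteome.gene_ids)
    labels: Dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path!s}:{lineno}: expected two tab-separated columns")
            gene_id, flag = parts[0].strip(), parts[1].strip().lower()
            if gene_id not in known:
                raise ValueError(
                    f"{path!s}:{lineno}: gene {gene_id!r} not present in proteome "
                    f"{proteome.genome_id!r}"
                )
            if gene_id in labels:
                raise ValueError(f"{path!s}:{lineno}: duplicate label for gene {gene_id!r}")
            if flag in _TRUE_FLAGS:
                labels[gene_id] = True
            elif flag in _FALSE_FLAGS:
                labels[gene_id] = False
            else:
                raise ValueError(
                    f"{path!s}:{lineno}: unrecognized essentiality flag {parts[1]!r}"
                )
    return LabelTable(proteome.genome_id, labels)


def write_labels(path: os.PathLike | str, table: LabelTable) -> None:
    """Write a label table as two-column TSV (flags ``1``/``0``)."""
    with open(path, "w") as fh:
        for gene_id in sorted(table.labels):
            fh.write(f"{gene_id}\t{1 if table.labels[gene_id] else 0}\n")


def write_scores(path: os.PathLike | str, table) -> None:
    """Write a finalized :class:`~orthoess.scoring.ScoreTable` as TSV.

    Rows are sorted by normalized score descending, ties broken by gene id
    ascending, so the byte output is deterministic for a given table.
    """
    order = sorted(
        range(len(table.gene_ids)),
        key=lambda i: (-table.normalized[i], table.gene_ids[i]),
    )
    with open(path, "w") as fh:
        fh.write(f"# threshold={table.threshold!r}\n")
        fh.write("gene_id\traw_score\tnormalized_score\tpredicted_label\n")
        for i in order:
            fh.write(
                f"{table.gene_ids[i]}\t{float(table.raw[i])!r}\t"
                f"{float(table.normalized[i])!r}\t"
                f"{1 if table.predicted[i] else 0}\n"
            )


def read_scores(path: os.PathLike | str):
    """Read a score table written by :func:`write_scores` back into memory."""
    from .scoring import ScoreTable  # deferred: io is imported by scoring

    threshold = None
    gene_ids: List[str] = []
    raw: List[float] = []
    normalized: List[float] = []
    predicted: List[bool] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("gene_id\t"):
                continue
            g, r, n, p = line.split("\t")
            gene_ids.append(g)
            raw.append(float(r))
            normalized.append(float(n))
            predicted.append(p == "1")
    if threshold is None:
        raise ValueError(f"{path!s}: missing threshold header")
    return ScoreTable(
        gene_ids=tuple(gene_ids),
        raw=tuple(raw),
        normalized=tuple(normalized),
        predicted=tuple(predicted),
        threshold=threshold,
    )
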