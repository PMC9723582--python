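"""Sequence I/O, the MSA container, and per-stage accounting.

FASTA/FASTQ records are read through Biopython's low-level iterators (with
added validation and line-number context) into a light :class:`SeqRecord`.
Sequences are uppercase-normalized on input and restricted to {A,C,G,T,N};
this is a DNA-only pipeline, so RNA alphabets ('U') are rejected.  Gaps are
always ``-``.  Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._align import GAP, drop_gap_only_columns

DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed sequence file; message names the offending location."""


@dataclass
class SeqRecord:
    """One sequence with optional Phred qualities and description."""

    id: str
    seq: str
    qual: list[int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.seq = normalize_seq(self.seq, context=self.id)
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(seq: str, context: str = "") -> str:
    """Uppercase-fold and validate a DNA string."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        where = f" in {context!r}" if context else ""
        raise ParseError(
            f"invalid DNA character(s) {sorted(bad)}{where}; "
            "allowed alphabet is A,C,G,T,N"
        )
    return seq


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file (Phred+33 qualities)."""
    path = Path(path)
    with open(path) as fh:
        n_done = 0
        try:
            for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                n_done = idx
                line = 4 * idx + 1
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path.name} line {line}: quality length "
                        f"{len(qual)} != sequence length {len(seq)}"
                    )
                rec_id, _, desc = title.partition(" ")
                try:
                    yield SeqRecord(
                        rec_id,
                        seq,
                        qual=[ord(c) - 33 for c in qual],
                        description=desc,
                    )
                except ParseError as exc:
                    raise ParseError(f"{path.name} line {line}: {exc}") from exc
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(
                f"{path.name} line {4 * n_done + 1}: {exc}"
            ) from exc


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file."""
    path = Path(path)
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rec_id, _, desc = title.partition(" ")
            if rec_id in seen:
                raise ParseError(f"{path.name}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            yield SeqRecord(rec_id, seq, description=desc)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write FASTA with a fixed wrap width; byte-deterministic."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            header = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write 4-line FASTQ (Phred+33; missing qualities default to Q20)."""
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [20] * len(rec.seq)
            header = f"@{rec.id} {rec.description}" if rec.description else f"@{rec.id}"
            fh.write(header + "\n" + rec.seq + "\n+\n")
            fh.write("".join(chr(q + 33) for q in qual) + "\n")


@dataclass
class Msa:
    """A rectangular gapped alignment over {A,C,G,T,N,-}."""

    row_ids: list[str]
    matrix: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.matrix):
            raise ValueError(
                f"{len(self.row_ids)} ids for {len(self.matrix)} rows"
            )
        if self.matrix:
            width = len(self.matrix[0])
            for rid, row in zip(self.row_ids, self.matrix):
                if len(row) != width:
                    raise ValueError(f"ragged MSA: row {rid!r} has length "
                                     f"{len(row)} != {width}")

    @property
    def width(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    @property
    def n_rows(self) -> int:
        return len(self.matrix)

    def row(self, row_id: str) -> str:
        return self.matrix[self.row_ids.index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return ungap(self.row(row_id))

    def compact(self) -> "Msa":
        """Drop all-gap columns."""
        return Msa(list(self.row_ids), drop_gap_only_columns(list(self.matrix)))

    def to_records(self) -> list[SeqRecord]:
        return [_GappedRecord(rid, row) for rid, row in zip(self.row_ids, self.matrix)]


class _GappedRecord(SeqRecord):
    """SeqRecord that tolerates the gap character (for MSA export)."""

    def __post_init__(self) -> None:  # gapped FASTA rows may contain '-'
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET - {GAP}
        if bad:
            raise ParseError(f"invalid character(s) {sorted(bad)} in {self.id!r}")


def msa_from_rows(ids: list[str], rows: list[str]) -> Msa:
    return Msa(list(ids), [r.upper() for r in rows])


def ungap(row: str) -> str:
    """Strip gap characters only."""
    return row.replace(GAP, "")


def write_msa_fasta(msa: Msa, path: str | Path, wrap: int = 60) -> None:
    write_fasta(msa.to_records(), path, wrap=wrap)


def read_msa_fasta(path: str | Path) -> Msa:
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            ids.append(title.partition(" ")[0])
            rows.append(seq.upper())
    return Msa(ids, rows)


class StageLedger:
    """Per-stage input/retained/discarded accounting.

    Conservation (``input == retained + sum(discarded)``) is enforced when a
    stage is closed and can be asserted at any time with :meth:`check`.
    """

    def __init__(self) -> None:
        self._stages: dict[str, dict] = {}
        self._order: list[str] = []

    def open_stage(self, name: str, n_input: int) -> None:
        if name in self._stages:
            raise ValueError(f"stage {name!r} already open")
        self._stages[name] = {"input": n_input, "retained": 0, "discarded": {}}
        self._order.append(name)

    def retain(self, stage: str, n: int = 1) -> None:
        self._stages[stage]["retained"] += n

    def discard(self, stage: str, reason: str, n: int = 1) -> None:
        d = self._stages[stage]["discarded"]
        d[reason] = d.get(reason, 0) + n

    def counts(self, stage: str) -> dict:
        return self._stages[stage]

    def check(self) -> None:
        for name, c in self._stages.items():
            total = c["retained"] + sum(c["discarded"].values())
            if total != c["input"]:
                raise AssertionError(
                    f"ledger conservation violated at stage {name!r}: "
                    f"input={c['input']} retained={c['retained']} "
                    f"discarded={c['discarded']}"
                )

    def table(self) -> pd.DataFrame:
        rows = []
        for name in self._order:
            c = self._stages[name]
            rows.append(
                {
                    "stage": name,
                    "input": c["input"],
                    "retained": c["retained"],
                    **{f"discarded_{k}": v for k, v in sorted(c["discarded"].items())},
                }
            )
        return pd.DataFrame(rows)
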