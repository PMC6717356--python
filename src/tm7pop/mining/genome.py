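"""Genome assemblies and protein query panels, with FASTA round-tripping."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """An assembly: ordered scaffolds with unique ids.

    Sequences are upper-case DNA over ``{A,C,G,T,N}``; runs of N represent
    assembly gaps.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("scaffold ids must be unique")
        cleaned = []
        for rid, seq in self.records:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"scaffold {rid!r} is empty")
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"scaffold {rid!r} contains invalid characters {bad}")
            cleaned.append((rid, seq))
        self.records = cleaned
        self._index = {rid: seq for rid, seq in cleaned}

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, scaffold_id: str) -> str:
        return self._index[scaffold_id]

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        return cls(records=[(r.id, str(r.seq)) for r in _read_fasta(path)])

    def to_fasta(self, path: str | Path) -> None:
        _write_fasta(path, self.records)


@dataclass
class QueryPanel:
    """Reference proteins used as translated-search queries.

    Each entry may carry a label (e.g. ``receptor`` vs ``decoy``) encoded as
    a suffix ``id|label``; :meth:`label_of` recovers it.
    """

    proteins: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("query panel must not be empty")
        cleaned = []
        for pid, seq in self.proteins:
            seq = seq.upper().rstrip("*")
            bad = set(seq) - _AA_ALPHABET
            if bad:
                raise ValueError(f"protein {pid!r} contains invalid characters {bad}")
            cleaned.append((pid, seq))
        self.proteins = cleaned

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    @staticmethod
    def label_of(protein_id: str) -> str:
        return protein_id.rsplit("|", 1)[1] if "|" in protein_id else ""

    @classmethod
    def from_fasta(cls, path: str | Path) -> "QueryPanel":
        return cls(proteins=[(r.id, str(r.seq)) for r in _read_fasta(path)])

    def to_fasta(self, path: str | Path) -> None:
        _write_fasta(path, self.proteins)


def _read_fasta(path: str | Path) -> Iterable[SeqRecord]:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fasta")
    else:
        yield from SeqIO.parse(str(path), "fasta")


def _write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")
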