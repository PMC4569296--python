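"""Shared file-format I/O: FASTA, FASTQ (Phred+33), aligned FASTA, YAML config.

FASTA and MSA reading/writing delegate to Biopython; FASTQ goes through a
thin quartet reader so that malformed or truncated records can be reported
with their record index, which the pipeline's error contract requires.
All readers are gzip-transparent and tolerate CRLF line endings.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Malformed FASTQ; the message names the 0-based record index."""


@dataclass
class QualityRead:
    """One sequencing read with per-base Phred scores.

    ``mate`` is 1 or 2 for paired data (0 when unpaired); ``qual`` holds
    integer Phred scores, Phred+33 encodable.
    """

    id: str
    mate: int
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}")
        bad = set(self.seq.upper()) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")

    @property
    def qual_string(self) -> str:
        return "".join(chr(q + 33) for q in self.qual)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # zero the mtime/name header fields so identical content
            # gives byte-identical files (rerun reproducibility)
            raw = gzip.GzipFile(fileobj=open(path, "wb"), mode="wb",
                                filename="", mtime=0)
            return _io.TextIOWrapper(raw) if "t" in mode else raw
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; gzip-transparent."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Yield QualityRead records from a (possibly gzipped) FASTQ file.

    Mate numbers are taken from trailing ``/1`` / ``/2`` id suffixes when
    present.  Raises FastqFormatError naming the record index on a
    malformed or truncated quartet.
    """
    with _open_text(path) as fh:
        yield from parse_fastq(fh)


def parse_fastq(fh) -> Iterator[QualityRead]:
    idx = 0
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\r\n")
        if not header:  # tolerate trailing blank lines
            continue
        lines = [fh.readline().rstrip("\r\n") for _ in range(3)]
        if not header.startswith("@"):
            raise FastqFormatError(f"record {idx}: header {header[:30]!r} "
                                   "does not start with '@'")
        seq, plus, qual = lines
        if not plus.startswith("+"):
            raise FastqFormatError(f"record {idx}: separator line missing")
        if not qual or not seq:
            raise FastqFormatError(f"record {idx}: truncated record")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {idx}: sequence/quality length mismatch")
        name = header[1:].split()[0]
        mate = 0
        if name.endswith("/1"):
            name, mate = name[:-2], 1
        elif name.endswith("/2"):
            name, mate = name[:-2], 2
        try:
            read = QualityRead(id=name, mate=mate, seq=seq.upper(),
                               qual=[ord(c) - 33 for c in qual])
        except ValueError as exc:
            raise FastqFormatError(f"record {idx}: {exc}") from exc
        yield read
        idx += 1


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    """Write Phred+33 FASTQ with /1 /2 mate suffixes; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate in (1, 2) else ""
            fh.write(f"@{r.id}{suffix}\n{r.seq}\n+\n{r.qual_string}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# MSA and config

def read_msa(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA; rows are checked for equal length."""
    with _open_text(path) as fh:
        aln = AlignIO.read(fh, "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def read_config(path: str | Path) -> dict:
    with _open_text(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def sha256_of(path: str | Path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
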