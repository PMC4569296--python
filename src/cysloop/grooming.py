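"""Phred-quality read grooming.

A read is retained only if it contains at least ``min_run`` contiguous
bases (default 80) with Phred score at or above ``min_q`` (default 20,
i.e. score > 19); it is trimmed to that run.  Mates pass or fail
independently.  'N' bases count as Phred 0.  The groomed database carries
a terminal k-mer index over both orientations for the walker's overlap
lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io import QualityRead, read_fastq, revcomp, write_fasta, read_fasta
from .params import DEFAULT_PARAMS, PipelineParams


def longest_highq_run(qual: Iterable[int], min_q: int) -> tuple[int, int]:
    """Longest maximal run with all scores >= min_q; leftmost on ties.

    Returns a 0-based half-open interval; (0, 0) when no base qualifies.
    """
    best_start = best_end = 0
    run_start = None
    for i, q in enumerate(qual):
        if q >= min_q:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_end - best_start:
                best_start, best_end = run_start, i
            run_start = None
    if run_start is not None:
        i = i + 1  # sequence length
        if i - run_start > best_end - best_start:
            best_start, best_end = run_start, i
    return best_start, best_end


def groom_read(read: QualityRead,
               params: PipelineParams = DEFAULT_PARAMS) -> QualityRead | None:
    """Trim a read to its longest high-quality run; None if the run is
    shorter than min_run."""
    qual_eff = [0 if b == "N" else q for b, q in zip(read.seq, read.qual)]
    start, end = longest_highq_run(qual_eff, params.min_q)
    if end - start < params.min_run:
        return None
    if (start, end) == (0, len(read.seq)):
        return read
    return QualityRead(id=read.id, mate=read.mate,
                       seq=read.seq[start:end], qual=read.qual[start:end])


@dataclass
class GroomStats:
    input: int = 0
    retained: int = 0
    trimmed: int = 0
    rejected: int = 0


@dataclass
class GroomedReadDB:
    """Quality-filtered, trimmed reads with an overlap k-mer index.

    The index maps the first k bases of every stored read, in both the
    forward and reverse-complement orientation, to (read index, orientation)
    pairs; the walker anchors terminal overlaps through it.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)  # (id, seq)
    stats: GroomStats = field(default_factory=GroomStats)
    _index: dict | None = None
    _index_k: int | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def add(self, read: QualityRead) -> None:
        suffix = f"/{read.mate}" if read.mate in (1, 2) else ""
        self.reads.append((read.id + suffix, read.seq))
        self._index = None

    def oriented_seq(self, idx: int, orient: str) -> str:
        seq = self.reads[idx][1]
        return seq if orient == "+" else revcomp(seq)

    def prefix_index(self, k: int) -> dict[str, list[tuple[int, str]]]:
        """k-mer -> [(read idx, orientation)] keyed on oriented prefixes."""
        if self._index is not None and self._index_k == k:
            return self._index
        index: dict[str, list[tuple[int, str]]] = {}
        for i, (_rid, seq) in enumerate(self.reads):
            if len(seq) < k:
                continue
            index.setdefault(seq[:k], []).append((i, "+"))
            rc = revcomp(seq)
            index.setdefault(rc[:k], []).append((i, "-"))
        self._index, self._index_k = index, k
        return index

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reads, directory / "groomed.fasta")
        s = self.stats
        (directory / "stats.tsv").write_text(
            "input\tretained\ttrimmed\trejected\n"
            f"{s.input}\t{s.retained}\t{s.trimmed}\t{s.rejected}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "GroomedReadDB":
        directory = Path(directory)
        db = cls(reads=read_fasta(directory / "groomed.fasta"))
        lines = (directory / "stats.tsv").read_text().splitlines()
        vals = [int(x) for x in lines[1].split("\t")]
        db.stats = GroomStats(*vals)
        return db


def groom_reads(reads: Iterable[QualityRead],
                params: PipelineParams = DEFAULT_PARAMS) -> GroomedReadDB:
    """Groom an in-memory read stream into a database."""
    db = GroomedReadDB()
    for read in reads:
        db.stats.input += 1
        groomed = groom_read(read, params)
        if groomed is None:
            db.stats.rejected += 1
            continue
        db.stats.retained += 1
        if len(groomed.seq) < len(read.seq):
            db.stats.trimmed += 1
        db.add(groomed)
    return db


def groom_library(fastq_paths: Iterable[str | Path],
                  params: PipelineParams = DEFAULT_PARAMS) -> GroomedReadDB:
    """Groom one library given its FASTQ file(s); mates are independent."""
    def _stream():
        for path in fastq_paths:
            yield from read_fastq(path)
    return groom_reads(_stream(), params)
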