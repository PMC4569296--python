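"""Main-ORF derivation, protein translation, molecular weight, poly-A calls.

The main open reading frame (mORF) of an assembled transcript is the longest
ATG-initiated ORF ending in a stop codon over all six frames; its
translation (stop excluded) is the subunit protein whose residue count and
average molecular weight populate the per-transcript report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from .io import revcomp

_STOPS = ("TAA", "TAG", "TGA")


class OrfError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """An assembled transcript with its mORF and translated protein.

    ``morf`` is a 0-based half-open interval on ``seq`` (forward
    coordinates) that includes the STOP codon; ``strand`` says which strand
    the mORF is read from; ``polya`` is the terminal poly-A interval when
    detected.
    """

    id: str
    seq: str
    morf: tuple[int, int]
    strand: str
    protein: str
    polya: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        start, end = self.morf
        if (end - start) % 3:
            raise ValueError(f"{self.id}: mORF length not divisible by 3")
        if len(self.protein) != (end - start) // 3 - 1:
            raise ValueError(f"{self.id}: protein length inconsistent with mORF")

    @property
    def morf_seq(self) -> str:
        start, end = self.morf
        sub = self.seq[start:end]
        return sub if self.strand == "+" else revcomp(sub)


def _scan_frames(seq: str):
    """Yield (length_nt, start, end, strand) for every ATG..STOP span.

    Coordinates are on the forward sequence, half-open, stop included.
    """
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            starts: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in _STOPS:
                    if starts:
                        first = starts[0]
                        end = i + 3
                        if strand == "+":
                            yield end - first, first, end, "+"
                        else:
                            yield end - first, n - end, n - first, "-"
                    starts = []


def find_morf(seq: str, id: str = "transcript",
              min_codons: int = 50) -> TranscriptModel:
    """Locate the main ORF: longest ATG-initiated ORF over six frames.

    Ties break by earliest start on the forward sequence, then + strand.
    Raises OrfError when no ORF reaches ``min_codons`` codons (start codon
    included, stop excluded).
    """
    seq = seq.upper()
    if len(seq) < 33:
        raise OrfError(f"{id}: sequence shorter than 33 nt")
    best = None
    for length, start, end, strand in _scan_frames(seq):
        key = (-length, start, 0 if strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, start, end, strand)
    if best is None or (best[2] - best[1]) // 3 - 1 < min_codons:
        raise OrfError(f"{id}: no ORF of >= {min_codons} codons found")
    _, start, end, strand = best
    sub = seq[start:end] if strand == "+" else revcomp(seq[start:end])
    protein = str(Seq(sub[:-3]).translate())
    if "*" in protein:
        raise OrfError(f"{id}: internal stop in candidate mORF")
    model = TranscriptModel(id=id, seq=seq, morf=(start, end), strand=strand,
                            protein=protein)
    model.polya = detect_polya(seq)
    return model


def molecular_weight(protein: str) -> float:
    """Average molecular weight of a peptide in kDa (residues + one water)."""
    if not protein:
        raise ValueError("empty protein")
    if any(c not in "ACDEFGHIKLMNPQRSTVWY" for c in protein):
        bad = sorted(set(protein) - set("ACDEFGHIKLMNPQRSTVWY"))
        raise ValueError(f"unknown residues {bad} (X not permitted)")
    return _bio_mw(Seq(protein), seq_type="protein", monoisotopic=False) / 1000.0


def detect_polya(seq: str, min_len: int = 15,
                 max_mismatch: int = 1) -> tuple[int, int] | None:
    """Terminal 3' poly-A run of >= min_len allowing <= max_mismatch non-A.

    Returns the longest qualifying suffix interval (starting on an A),
    or None.
    """
    seq = seq.upper()
    n = len(seq)
    mismatches = 0
    best = None
    for i in range(n - 1, -1, -1):
        if seq[i] != "A":
            mismatches += 1
            if mismatches > max_mismatch:
                break
        if seq[i] == "A" and n - i >= min_len:
            best = (i, n)
    return best


def transcript_report(models: list[TranscriptModel],
                      cleavage: dict[str, int] | None = None):
    """Per-transcript table: residue count, MW (kDa), poly-A call.

    ``cleavage`` optionally maps transcript id to a signal-peptide cleavage
    position (0-based residue index of the first mature residue) so the
    report can also show mature-protein lengths and weights.
    """
    import pandas as pd

    cleavage = cleavage or {}
    rows = []
    for m in models:
        row = {
            "id": m.id,
            "n_aa": len(m.protein),
            "mw_kda": round(molecular_weight(m.protein), 3),
            "mw_kda_rounded": round(molecular_weight(m.protein)),
            "morf_start": m.morf[0],
            "morf_end": m.morf[1],
            "strand": m.strand,
            "polya": "" if m.polya is None else f"{m.polya[0]}-{m.polya[1]}",
        }
        if m.id in cleavage:
            mature = m.protein[cleavage[m.id]:]
            row["mature_n_aa"] = len(mature)
            row["mature_mw_kda"] = round(molecular_weight(mature), 3)
        rows.append(row)
    return pd.DataFrame(rows)
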