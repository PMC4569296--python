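"""Actin-relative mRNA abundance from ungapped read matching.

A read counts toward a gene when its best ungapped placement against the
gene's mORF (either orientation, read fully contained) reaches at least 90
identical nucleotides per 100 (proportionally for trimmed reads: ceil of
0.9 x read length).  Raw counts are normalized by mORF length and expressed
relative to the actin reference, whose own relative abundance is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grooming import GroomedReadDB
from .io import revcomp
from .params import DEFAULT_PARAMS, PipelineParams


@dataclass
class AbundanceRecord:
    gene: str
    library: str
    reads_tested: int
    raw_count: int
    morf_length: int
    relative_abundance: float


def _ident_threshold(read_len: int, params: PipelineParams) -> int:
    return math.ceil(params.count_min_ident / params.count_window * read_len)


def best_identity(read: str, morf: str) -> int:
    """Maximum identities over all ungapped, fully-contained placements of
    the read (either orientation) on the mORF."""
    n, L = len(read), len(morf)
    if n > L:
        return 0
    marr = np.frombuffer(morf.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(marr, n)
    best = 0
    for seq in (read, revcomp(read)):
        rarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        best = max(best, int((windows == rarr).sum(axis=1).max()))
    return best


def read_matches_gene(read: str, morf: str,
                      params: PipelineParams = DEFAULT_PARAMS) -> bool:
    """Does the read score as derived from the gene under the 90/100 rule?"""
    if len(read) < 40:
        raise ValueError("read shorter than 40 nt")
    return best_identity(read.upper(), morf.upper()) >= \
        _ident_threshold(len(read), params)


def _seed_k(read_lens: set[int], params: PipelineParams) -> int:
    """Largest exact k-mer guaranteed (pigeonhole) inside any qualifying
    placement across the read lengths present."""
    ks = []
    for n in read_lens:
        t = _ident_threshold(n, params)
        m = n - t
        ks.append(n if m == 0 else math.ceil(t / (m + 1)))
    return max(4, min(min(ks), 31))


def count_genes(db: GroomedReadDB, morfs: dict[str, str],
                params: PipelineParams = DEFAULT_PARAMS) -> dict[str, int]:
    """Raw per-gene counts over the whole database in one pass.

    Exact algorithm: a k-mer prefilter (any placement with enough identities
    must contain an exact aligned k-mer, by pigeonhole) proposes offsets,
    which are then verified by full ungapped identity counting.  Each read
    counts at most once per gene.
    """
    morfs = {g: m.upper() for g, m in morfs.items()}
    read_lens = {len(s) for _, s in db.reads}
    if not read_lens:
        return {g: 0 for g in morfs}
    k = _seed_k(read_lens, params)
    index: dict[str, list[tuple[str, int]]] = {}
    for gene, morf in morfs.items():
        for p in range(len(morf) - k + 1):
            index.setdefault(morf[p:p + k], []).append((gene, p))
    counts = {g: 0 for g in morfs}
    lengths = {g: len(m) for g, m in morfs.items()}
    for _rid, seq in db.reads:
        n = len(seq)
        thr = _ident_threshold(n, params)
        matched: set[str] = set()
        for oriented in (seq, revcomp(seq)):
            candidates: dict[str, set[int]] = {}
            for j in range(n - k + 1):
                for gene, p in index.get(oriented[j:j + k], ()):
                    off = p - j
                    if 0 <= off <= lengths[gene] - n:
                        candidates.setdefault(gene, set()).add(off)
            for gene, offs in candidates.items():
                if gene in matched:
                    continue
                morf = morfs[gene]
                for off in offs:
                    window = morf[off:off + n]
                    ident = sum(a == b for a, b in zip(oriented, window))
                    if ident >= thr:
                        matched.add(gene)
                        break
        for gene in matched:
            counts[gene] += 1
    return counts


def count_gene(db: GroomedReadDB, morf: str,
               params: PipelineParams = DEFAULT_PARAMS) -> int:
    """Reads in the database matching one gene's mORF."""
    return count_genes(db, {"gene": morf}, params)["gene"]


def relative_abundance(raw_counts: dict[str, int],
                       morf_lengths: dict[str, int],
                       actin_id: str,
                       library: str = "library",
                       reads_tested: int | None = None
                       ) -> list[AbundanceRecord]:
    """Length-normalized counts expressed relative to the actin reference.

    RA_g = (count_g / length_g) / (count_actin / length_actin); raises when
    the actin count is zero (undefined reference).
    """
    if actin_id not in raw_counts:
        raise KeyError(f"actin reference {actin_id!r} missing from counts")
    if raw_counts[actin_id] == 0:
        raise ZeroDivisionError("actin reference has zero counts; "
                                "relative abundance undefined")
    actin_density = raw_counts[actin_id] / morf_lengths[actin_id]
    n_tested = reads_tested if reads_tested is not None else -1
    records = []
    for gene in raw_counts:
        density = raw_counts[gene] / morf_lengths[gene]
        ra = 1.0 if gene == actin_id else density / actin_density
        records.append(AbundanceRecord(
            gene=gene, library=library, reads_tested=n_tested,
            raw_count=raw_counts[gene], morf_length=morf_lengths[gene],
            relative_abundance=ra))
    return records


def abundance_table(records: list[AbundanceRecord]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])


def plot_abundance(records: list[AbundanceRecord], path: str) -> None:
    """Log-scale bar chart of relative abundances per gene and library."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = abundance_table(records)
    pivot = df.pivot_table(index="gene", columns="library",
                           values="relative_abundance")
    ax = pivot.plot.bar(logy=True, figsize=(8, 4))
    ax.set_ylabel("abundance relative to actin")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
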