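"""Bait-driven seed discovery and transcriptome walking.

Seeds are groomed reads whose best ungapped six-frame translation scores
above threshold against a bait protein under a BLOSUM matrix.  A seed is
then grown by repeatedly appending reads that overlap the contig terminus
exactly over at least the current minimum overlap (initially 60 nt).  When
several extension pathways disagree the minimum overlap escalates in steps
of 10 up to 90 to eliminate the ambiguity; when nothing overlaps it relaxes
in steps of 10 down to 40.  Walking runs to exhaustion in the 5' direction
and, in the 3' direction, to the poly-A tail or until the complete coding
sequence and STOP codon are contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .grooming import GroomedReadDB
from .io import revcomp
from .orf import OrfError, TranscriptModel, detect_polya, find_morf
from .params import DEFAULT_PARAMS, PipelineParams


# ---------------------------------------------------------------------------
# Seed discovery

@dataclass
class BaitHit:
    read_id: str
    read_idx: int
    frame: int            # -3..+3 excluding 0; sign encodes strand
    score: float          # substitution-matrix sum of the best window
    matrix: str
    span: tuple[int, int]  # nt interval on the oriented read
    seed_seq: str          # the read, oriented to the matching strand


def _translate_frames(seq: str) -> list[tuple[int, str]]:
    out = []
    rc = revcomp(seq)
    for off in range(3):
        for frame, s in ((off + 1, seq), (-(off + 1), rc)):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            if sub:
                out.append((frame, str(Seq(sub).translate())))
    return out


class _BaitScorer:
    """Ungapped best-window scorer against one bait protein."""

    def __init__(self, bait: str, matrix_name: str):
        self.matrix_name = matrix_name
        mat = substitution_matrices.load(matrix_name)
        self.alphabet = str(mat.alphabet)
        self.lut = np.full(128, self.alphabet.index("X")
                           if "X" in self.alphabet else 0, dtype=np.int64)
        for i, a in enumerate(self.alphabet):
            self.lut[ord(a)] = i
        self.mat = np.asarray(mat, dtype=np.float64)
        self.bait_idx = self.lut[np.frombuffer(bait.encode(), np.uint8)]

    def best_window(self, peptide: str) -> tuple[float, int]:
        """(best score over all ungapped offsets, best diagonal id).

        Diagonal d corresponds to peptide position i aligning bait
        position i + d - (m - 1), m = len(peptide).
        """
        pep_idx = self.lut[np.frombuffer(peptide.encode(), np.uint8)]
        S = self.mat[self.bait_idx[:, None], pep_idx[None, :]]
        n, m = S.shape
        d = (np.arange(n)[:, None] - np.arange(m)[None, :] + m - 1)
        scores = np.bincount(d.ravel(), weights=S.ravel(), minlength=n + m - 1)
        best = int(np.argmax(scores))
        return float(scores[best]), best


def find_seeds(bait: str, db: GroomedReadDB,
               params: PipelineParams = DEFAULT_PARAMS) -> list[BaitHit]:
    """All reads whose best ungapped six-frame window scores >= threshold.

    Deterministic order: score descending, then read id.
    """
    if len(bait) < 10:
        raise ValueError("bait shorter than 10 residues")
    scorer = _BaitScorer(bait.upper(), params.blosum_name)
    hits: list[BaitHit] = []
    for idx, (rid, seq) in enumerate(db.reads):
        for frame, pep in _translate_frames(seq):
            if "*" in pep:  # stop codons cannot sit inside a coding window
                segments = pep.split("*")
            else:
                segments = [pep]
            base = 0
            for seg in segments:
                if len(seg) >= 5:
                    score, diag = scorer.best_window(seg)
                    if score >= params.bait_score_threshold:
                        m = len(seg)
                        lo = max(0, m - 1 - diag)
                        hi = min(m, m - 1 - diag + len(scorer.bait_idx))
                        off = abs(frame) - 1
                        aa_lo, aa_hi = base + lo, base + hi
                        span = (off + 3 * aa_lo, off + 3 * aa_hi)
                        oriented = seq if frame > 0 else revcomp(seq)
                        hits.append(BaitHit(
                            read_id=rid, read_idx=idx, frame=frame,
                            score=score, matrix=params.blosum_name,
                            span=span, seed_seq=oriented))
                base += len(seg) + 1
    best: dict[tuple[int, int], BaitHit] = {}
    for h in hits:
        key = (h.read_idx, 0 if h.frame > 0 else 1)
        if key not in best or h.score > best[key].score:
            best[key] = h
    out = sorted(best.values(), key=lambda h: (-h.score, h.read_id, h.frame))
    return out


# ---------------------------------------------------------------------------
# Overlap extension

@dataclass
class Extension:
    read_idx: int
    read_id: str
    orient: str           # orientation of the read against the contig sense
    overlap: int
    overhang: str         # bases appended 3' (or prepended 5', already
                          # flipped to contig coordinates)


@dataclass
class WalkState:
    contig: str
    direction: str                       # '5prime' | '3prime'
    current_min_overlap: int
    trace: list[dict] = field(default_factory=list)
    status: str = "extending"
    pathways: list[str] = field(default_factory=list)  # on ambiguity


def find_extensions(db: GroomedReadDB, terminus: str, min_overlap: int,
                    direction: str = "3prime",
                    params: PipelineParams = DEFAULT_PARAMS) -> list[Extension]:
    """All reads overlapping the contig terminus exactly over >= min_overlap
    nt (either orientation) that extend beyond it."""
    if len(terminus) < min_overlap:
        raise ValueError("terminus shorter than min_overlap")
    if direction == "5prime":
        flipped = find_extensions(db, revcomp(terminus), min_overlap,
                                  "3prime", params)
        return [Extension(e.read_idx, e.read_id,
                          "+" if e.orient == "-" else "-",
                          e.overlap, revcomp(e.overhang)) for e in flipped]
    k = params.overlap_min
    index = db.prefix_index(k)
    if not db.reads:
        return []
    max_read = max(len(s) for _, s in db.reads)
    out: list[Extension] = []
    for L in range(min_overlap, min(len(terminus), max_read - 1) + 1):
        i = len(terminus) - L
        for ridx, orient in index.get(terminus[i:i + k], ()):
            seq = db.oriented_seq(ridx, orient)
            if len(seq) > L and seq[:L] == terminus[i:]:
                out.append(Extension(ridx, db.reads[ridx][0], orient, L,
                                     seq[L:]))
    return out


def group_pathways(extensions: list[Extension]) -> list[tuple[str, list[Extension]]]:
    """Group candidates into pathways by overhang.

    A pathway is a distinct maximal overhang under the prefix partial
    order; candidates whose overhang is a prefix of a pathway's
    representative belong to it.  Sorted by representative.
    """
    overhangs = sorted({e.overhang for e in extensions})
    maximal = [o for o in overhangs
               if not any(other != o and other.startswith(o)
                          for other in overhangs)]
    return [(rep, [e for e in extensions if rep.startswith(e.overhang)])
            for rep in sorted(maximal)]


def extend_once(state: WalkState, db: GroomedReadDB,
                params: PipelineParams = DEFAULT_PARAMS) -> WalkState:
    """One adaptive extension step.

    A unique pathway appends its longest overhang and resets the threshold;
    multiple pathways escalate the threshold within this call (up to
    overlap_max, else status=ambiguous, pathways recorded); zero pathways
    relax it (down to overlap_min, else status=exhausted).  Relaxation or
    escalation that never reaches a unique pathway ends ambiguous/exhausted
    per the direction in which the search failed.
    """
    if state.status != "extending":
        return state
    # Work in the orientation where overhangs are appended 3', so that
    # prefix grouping of overhangs is the right comparison; a 5' walk is a
    # 3' walk on the reverse complement.
    flip = state.direction == "5prime"
    mode = None  # 'up' | 'down' once the first observation fixes it
    last_paths: list[tuple[str, list[Extension]]] = []

    def _report(paths):
        return [revcomp(rep) if flip else rep for rep, _ in paths]

    while True:
        terminus = revcomp(state.contig) if flip else state.contig
        exts = find_extensions(db, terminus, state.current_min_overlap,
                               "3prime", params)
        paths = group_pathways(exts)
        if len(paths) == 1:
            rep, members = paths[0]
            winner = max(members, key=lambda e: (len(e.overhang), e.overlap))
            orient = winner.orient
            if flip:
                state.contig = revcomp(rep) + state.contig
                orient = "+" if orient == "-" else "-"
            else:
                state.contig = state.contig + rep
            state.trace.append({
                "read_id": winner.read_id, "orient": orient,
                "overlap": winner.overlap, "overhang": len(rep),
                "threshold": state.current_min_overlap,
                "direction": state.direction,
            })
            state.current_min_overlap = params.overlap_init
            return state
        if len(paths) > 1:
            last_paths = paths
            if mode == "down":
                state.status = "ambiguous"
                state.pathways = _report(paths)
                return state
            mode = "up"
            if state.current_min_overlap + params.overlap_step <= params.overlap_max:
                state.current_min_overlap += params.overlap_step
                continue
            state.status = "ambiguous"
            state.pathways = _report(paths)
            return state
        # zero pathways
        if mode == "up":
            # escalation wiped out all candidates without isolating one
            state.status = "ambiguous"
            state.pathways = _report(last_paths)
            return state
        mode = "down"
        if state.current_min_overlap - params.overlap_step >= params.overlap_min:
            state.current_min_overlap -= params.overlap_step
            continue
        state.status = "exhausted"
        return state


# ---------------------------------------------------------------------------
# Full walk

@dataclass
class WalkResult:
    contig: str
    state5: WalkState
    state3: WalkState
    transcript: TranscriptModel | None

    @property
    def status3(self) -> str:
        return self.state3.status


def _stop_contained(contig: str, params: PipelineParams) -> bool:
    """Does the contig hold a complete forward-strand mORF with its STOP at
    least stop_margin nt from the 3' end?"""
    try:
        model = find_morf(contig, min_codons=params.min_orf_codons)
    except OrfError:
        return False
    return (model.strand == "+"
            and model.morf[1] + params.stop_margin <= len(contig))


def _finalize_3prime(state: WalkState, params: PipelineParams) -> None:
    if detect_polya(state.contig, params.polya_min_len,
                    params.polya_max_mismatch) is not None:
        state.status = "terminated_polya"
    elif state.status == "exhausted" and _stop_contained(state.contig, params):
        state.status = "terminated_stop"


def walk(seed: str, db: GroomedReadDB,
         params: PipelineParams = DEFAULT_PARAMS,
         continue_to_polya: bool = True) -> WalkResult:
    """Walk a seed in both directions.

    3' walking runs until the poly-A tail or exhaustion/ambiguity (with
    ``continue_to_polya=False`` it instead stops as soon as a complete mORF
    with STOP plus stop_margin nt is contained); 5' walking always runs to
    exhaustion/ambiguity.
    """
    seed = seed.upper()
    if len(seed) < params.overlap_init:
        raise ValueError(f"seed shorter than overlap_init "
                         f"({len(seed)} < {params.overlap_init})")
    state3 = WalkState(contig=seed, direction="3prime",
                       current_min_overlap=params.overlap_init)
    while state3.status == "extending":
        if not continue_to_polya and _stop_contained(state3.contig, params):
            state3.status = "terminated_stop"
            break
        extend_once(state3, db, params)
    _finalize_3prime(state3, params)

    state5 = WalkState(contig=state3.contig, direction="5prime",
                       current_min_overlap=params.overlap_init,
                       status="extending")
    while state5.status == "extending":
        extend_once(state5, db, params)

    contig = state5.contig
    try:
        transcript = find_morf(contig, id="contig",
                               min_codons=params.min_orf_codons)
    except OrfError:
        transcript = None
    return WalkResult(contig=contig, state5=state5, state3=state3,
                      transcript=transcript)
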