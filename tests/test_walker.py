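import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from cysloop import (MotifPlan, PipelineParams, QualityRead,
                     TranscriptomeSpec, groom_reads,
                     make_synthetic_transcriptome, tile_reads, walk)
from cysloop.io import revcomp
from cysloop.synthetic import _backtranslate
from cysloop.walker import (WalkState, extend_once, find_extensions,
                            find_seeds, group_pathways)
from conftest import random_dna


# ---------------------------------------------------------------------------
# Seed discovery

def brute_force_best_score(bait, read, matrix):
    """Independent six-frame ungapped window scan with dict lookups."""
    mat = substitution_matrices.load(matrix)
    best = None
    for s in (read, revcomp(read)):
        for off in range(3):
            sub = s[off:len(s) - (len(s) - off) % 3]
            pep = str(Seq(sub).translate())
            for seg in pep.split("*"):
                if len(seg) < 5:
                    continue
                m, n = len(seg), len(bait)
                for shift in range(-(m - 1), n):
                    score = 0.0
                    for j in range(m):
                        i = j + shift
                        if 0 <= i < n:
                            score += mat[bait[i], seg[j]]
                    best = score if best is None else max(best, score)
    return best


def test_find_seeds_identity_hit(rng, tiled_db, small_truth):
    """A read back-translated from a bait segment scores its self-score."""
    bait = small_truth.transcript("g00").protein[50:110]
    read_nt = _backtranslate(bait[10:43], rng)[:-3]  # strip stop codon
    db = groom_reads([QualityRead("self", 0, read_nt, [38] * len(read_nt))])
    hits = find_seeds(bait, db)
    assert len(hits) >= 1
    mat = substitution_matrices.load("BLOSUM62")
    self_score = sum(mat[a, a] for a in bait[10:43])
    assert hits[0].score == self_score


def test_find_seeds_matches_brute_force(rng, small_truth):
    bait = small_truth.transcript("g00").protein[40:120]
    reads = tile_reads(small_truth.transcript("g00").seq, 100, 40)[:6]
    reads += [QualityRead(f"rand{i}", 0, random_dna(rng, 100), [38] * 100)
              for i in range(6)]
    db = groom_reads(reads)
    params = PipelineParams(bait_score_threshold=-1e9)
    hits: dict[str, float] = {}
    for h in find_seeds(bait, db, params):  # one hit per strand; take best
        hits[h.read_id] = max(hits.get(h.read_id, float("-inf")), h.score)
    for rid, seq in db.reads:
        expected = brute_force_best_score(bait, seq, "BLOSUM62")
        assert hits[rid] == pytest.approx(expected)


def test_find_seeds_null_distribution(rng):
    """Random reads vs an unrelated bait never reach a 20-mer self-score."""
    bait = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                   for i in rng.integers(0, 20, 60))
    mat = substitution_matrices.load("BLOSUM62")
    threshold = sum(mat[a, a] for a in bait[:20])
    reads = [QualityRead(f"r{i}", 0, random_dna(rng, 100), [38] * 100)
             for i in range(300)]
    db = groom_reads(reads)
    params = PipelineParams(bait_score_threshold=float(threshold))
    assert find_seeds(bait, db, params) == []


def test_find_seeds_deterministic_order(tiled_db, small_truth):
    bait = small_truth.transcript("g01").protein[40:140]
    h1 = find_seeds(bait, tiled_db)
    h2 = find_seeds(bait, tiled_db)
    assert [(h.read_id, h.score) for h in h1] == \
        [(h.read_id, h.score) for h in h2]
    scores = [h.score for h in h1]
    assert scores == sorted(scores, reverse=True)


def test_find_seeds_rejects_short_bait(tiled_db):
    with pytest.raises(ValueError, match="bait"):
        find_seeds("MKWVT", tiled_db)


# ---------------------------------------------------------------------------
# Extension candidates and pathways

def brute_force_extensions(db, terminus, min_overlap):
    out = set()
    for idx, (rid, seq) in enumerate(db.reads):
        for orient in "+-":
            s = seq if orient == "+" else revcomp(seq)
            for L in range(min_overlap, min(len(terminus), len(s) - 1) + 1):
                if s[:L] == terminus[-L:]:
                    out.add((rid, orient, L, s[L:]))
    return out


def test_find_extensions_matches_brute_force(rng):
    transcript = random_dna(rng, 600)
    reads = tile_reads(transcript, 100, 7, id_prefix="t")
    reads += [QualityRead(f"junk{i}", 0, random_dna(rng, 100), [38] * 100)
              for i in range(10)]
    db = groom_reads(reads)
    terminus = transcript[:320]
    for min_overlap in (40, 60, 90):
        got = {(e.read_id, e.orient, e.overlap, e.overhang)
               for e in find_extensions(db, terminus, min_overlap)}
        assert got == brute_force_extensions(db, terminus, min_overlap)


def test_single_tiling_read_is_one_pathway(rng):
    terminus = random_dna(rng, 200)
    read = terminus[-60:] + random_dna(rng, 40)
    db = groom_reads([QualityRead("r", 0, read, [38] * 100)])
    exts = find_extensions(db, terminus, 60)
    assert len(group_pathways(exts)) == 1


def test_divergent_overhangs_are_two_pathways(rng):
    terminus = random_dna(rng, 200)
    tail = terminus[-60:]
    r1 = tail + "A" + random_dna(rng, 39)
    r2 = tail + "C" + random_dna(rng, 39)
    db = groom_reads([QualityRead("r1", 0, r1, [38] * 100),
                      QualityRead("r2", 0, r2, [38] * 100)])
    paths = group_pathways(find_extensions(db, terminus, 60))
    assert len(paths) == 2


def test_prefix_compatible_overhangs_share_a_pathway(rng):
    terminus = random_dna(rng, 200)
    long_read = terminus[-60:] + random_dna(rng, 40)
    short_read = terminus[-80:] + long_read[60:80]  # overhang is a prefix
    db = groom_reads([QualityRead("long", 0, long_read, [38] * 100),
                      QualityRead("short", 0, short_read, [38] * 100)])
    paths = group_pathways(find_extensions(db, terminus, 60))
    assert len(paths) == 1
    rep, members = paths[0]
    assert rep == long_read[60:]
    assert {e.read_id for e in members} == {"long", "short"}


def test_escalation_resolves_conflict_at_70(rng):
    contig = random_dna(rng, 200)
    good = contig[-75:] + random_dna(rng, 25)
    decoy = contig[-60:] + random_dna(rng, 40)
    db = groom_reads([QualityRead("good", 0, good, [38] * 100),
                      QualityRead("decoy", 0, decoy, [38] * 100)])
    assert len(group_pathways(find_extensions(db, contig, 60))) == 2
    state = WalkState(contig=contig, direction="3prime",
                      current_min_overlap=60)
    state = extend_once(state, db)
    assert state.status == "extending"
    assert state.trace[-1]["read_id"] == "good"
    assert state.trace[-1]["threshold"] == 70
    assert state.contig == contig + good[75:]
    assert state.current_min_overlap == 60  # reset after success


def test_relaxation_then_exhaustion(rng):
    contig = random_dna(rng, 200)
    # a single read overlapping by only 45 nt: found after relaxing to 40
    read = contig[-45:] + random_dna(rng, 55)
    db = groom_reads([QualityRead("deep", 0, read, [38] * 100)])
    state = WalkState(contig=contig, direction="3prime",
                      current_min_overlap=60)
    state = extend_once(state, db)
    assert state.status == "extending"
    assert state.trace[-1]["threshold"] <= 50
    # empty database exhausts at the floor
    state2 = WalkState(contig=contig, direction="3prime",
                       current_min_overlap=60)
    state2 = extend_once(state2, groom_reads([]))
    assert state2.status == "exhausted"


# ---------------------------------------------------------------------------
# Full walks

def test_walk_reconstructs_truth_exactly(small_truth, tiled_db):
    for gene in ("g00", "g01", "g02"):
        tx = small_truth.transcript(gene)
        result = walk(tx.seq[150:250], tiled_db)
        assert result.contig == tx.seq
        assert result.status3 == "terminated_polya"
        assert result.state5.status == "exhausted"
        assert result.transcript.morf == tx.morf
        assert result.transcript.protein == tx.protein


def test_walk_trace_overhangs_sum_to_growth(small_truth, tiled_db):
    tx = small_truth.transcript("g00")
    seed = tx.seq[150:250]
    result = walk(seed, tiled_db)
    grown = sum(t["overhang"] for t in
                result.state3.trace + result.state5.trace)
    assert len(result.contig) - len(seed) == grown
    assert seed in result.contig


def test_walk_accepted_reads_are_contig_substrings(small_truth, tiled_db):
    tx = small_truth.transcript("g00")
    result = walk(tx.seq[150:250], tiled_db)
    by_id = dict(tiled_db.reads)
    for step in result.state3.trace + result.state5.trace:
        seq = by_id[step["read_id"]]
        assert seq in result.contig or revcomp(seq) in result.contig


def test_walk_stop_termination_without_polya():
    plans = {"g00": MotifPlan(polya_length=0)}
    spec = TranscriptomeSpec(n_genes=1, include_actin=False,
                             motif_plan=plans, rng_seed=9, error_rate=0.0,
                             utr3_range=(60, 80))
    truth = make_synthetic_transcriptome(spec)
    tx = truth.transcript("g00")
    db = groom_reads(tile_reads(tx.seq, 100, 3))
    result = walk(tx.seq[200:300], db)
    assert result.contig == tx.seq
    assert result.status3 == "terminated_stop"
    # stopping at the mORF instead of walking on is also supported
    early = walk(tx.seq[200:300], db, continue_to_polya=False)
    assert early.status3 == "terminated_stop"
    assert len(early.contig) <= len(tx.seq)


def test_walk_shared_repeat_reports_ambiguity(rng):
    repeat = random_dna(rng, 95)
    t1 = random_dna(rng, 150) + repeat + random_dna(rng, 400)
    t2 = random_dna(rng, 150) + repeat + random_dna(rng, 400)
    reads = tile_reads(t1, 100, 1, id_prefix="t1") + \
        tile_reads(t2, 100, 1, id_prefix="t2")
    db = groom_reads(reads)
    result = walk(t1[:100], db)
    assert result.status3 == "ambiguous"
    assert len(result.state3.pathways) >= 2
    # the conflict survives every threshold up to the ceiling
    terminus = result.state3.contig
    for thr in (60, 70, 80, 90):
        paths = group_pathways(find_extensions(db, terminus, thr))
        assert len(paths) >= 2


def test_walk_threshold_monotonicity(rng, tiled_db, small_truth):
    """Pathway count never increases when the overlap threshold rises."""
    tx = small_truth.transcript("g00")
    terminus = tx.seq[:400]
    counts = [len(group_pathways(find_extensions(tiled_db, terminus, thr)))
              for thr in (40, 50, 60, 70, 80, 90)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_walk_determinism(small_truth, tiled_db):
    tx = small_truth.transcript("g01")
    r1 = walk(tx.seq[150:250], tiled_db)
    r2 = walk(tx.seq[150:250], tiled_db)
    assert r1.contig == r2.contig
    assert r1.state3.trace == r2.state3.trace
    assert r1.state5.trace == r2.state5.trace


def test_walk_rejects_short_seed(tiled_db):
    with pytest.raises(ValueError, match="seed"):
        walk("ACGT" * 10, tiled_db)
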