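"""Ground-truth transcriptome generation and paired-end read simulation.

The generator emulates the study conditions the pipeline was built for: a
small set of transcripts with Cys-loop subunit architecture (signal region,
ligand-binding loops, the signature Cys-loop, TM1-TM4 with planted TM2
prime-position residues, STOP codon and poly-A tail), one high-abundance
actin-like reference gene, per-library copy numbers, uniform substitution
errors, and two-state Phred quality strings with contiguous low-quality
runs that exercise the grooming rule.

Every planted feature is recorded so downstream stages can be scored
against the truth, and proteins are built on the same reference scaffold
the annotator anchors against, which makes planted motifs recoverable by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import scaffold
from .annotate import (class_from_features, par_motif_from_primes,
                       pharmacology_from_primes, selectivity_from_primes)
from .io import QualityRead, read_fasta, revcomp, write_fasta, write_fastq
from .orf import TranscriptModel, detect_polya, find_morf

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_table.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
del _codon, _aa, _table


@dataclass(frozen=True)
class QualityModel:
    """Two-state per-base Markov quality model.

    Bases sit in a high state (mean ``high_q``) or a low state (mean
    ``low_q``); ``tail_prob`` is the per-base chance of dropping into the
    low state and ``recovery_prob`` of climbing back, which yields
    realistic contiguous low-quality runs.  The default tail probability
    makes the grooming rule retain roughly half of 100-nt reads, emulating
    the retention the original libraries showed.
    """

    high_q: float = 38.0
    low_q: float = 12.0
    q_sd: float = 2.0
    tail_prob: float = 0.01
    recovery_prob: float = 0.25


@dataclass
class MotifPlan:
    """Planted features for one Cys-loop gene."""

    cys_loop_gap: int = scaffold.DEFAULT_CYS_LOOP_GAP
    second_cys_loop: bool = False
    vicinal_cc: bool = False
    tm_count: int = 4
    tm2_prime_residues: dict[int, str] = field(default_factory=dict)
    polya_length: int = 25

    def __post_init__(self) -> None:
        if self.tm_count not in (0, 4):
            raise ValueError("tm_count must be 0 or 4")
        if self.tm_count == 0 and self.tm2_prime_residues:
            raise ValueError(
                "tm2_prime_residues given with tm_count=0 is inconsistent")
        if not 8 <= self.cys_loop_gap <= 16:
            raise ValueError("cys_loop_gap outside supported range 8..16")
        for k, res in self.tm2_prime_residues.items():
            if not (-2 <= int(k) <= 23):
                raise ValueError(f"prime index {k} outside -2..23")
            if res not in "ACDEFGHIKLMNPQRSTVWY":
                raise ValueError(f"invalid residue {res!r} at prime {k}")
        if self.polya_length < 0:
            raise ValueError("polya_length must be >= 0")


@dataclass
class TranscriptomeSpec:
    """Conditions for one synthetic truth.

    ``n_genes`` counts non-actin genes; an actin-like reference is appended
    when ``include_actin``.  Genes named in ``motif_plan`` get the Cys-loop
    architecture; the rest are generic protein-coding genes with mORF
    lengths drawn from ``gene_length_range`` (nt).
    """

    n_genes: int = 4
    gene_length_range: tuple[int, int] = (900, 1500)
    include_actin: bool = True
    copy_numbers: dict[str, dict[str, int]] | None = None
    motif_plan: dict[str, MotifPlan] = field(default_factory=dict)
    rng_seed: int = 0
    divergence: float = 0.05
    utr5_range: tuple[int, int] = (60, 120)
    utr3_range: tuple[int, int] = (40, 80)
    generic_polya_length: int = 25
    error_rate: float = 0.005
    quality_model: QualityModel = field(default_factory=QualityModel)
    libraries: tuple[str, ...] = ("brain", "hypodermis")

    def gene_ids(self) -> list[str]:
        ids = [f"g{i:02d}" for i in range(self.n_genes)]
        if self.include_actin:
            ids.append("actin")
        return ids

    def validate(self) -> None:
        ids = set(self.gene_ids())
        unknown = set(self.motif_plan) - ids
        if unknown:
            raise ValueError(f"motif_plan names unknown genes {sorted(unknown)}")
        if "actin" in self.motif_plan:
            raise ValueError("the actin reference cannot carry a motif plan")
        if self.gene_length_range[0] < 300:
            raise ValueError("gene lengths must be >= 3x read length (300 nt)")
        if self.copy_numbers is not None:
            for lib, per_gene in self.copy_numbers.items():
                missing = ids - set(per_gene)
                if missing:
                    raise ValueError(
                        f"library {lib}: missing copy numbers for {sorted(missing)}")
                if any(c < 1 for c in per_gene.values()):
                    raise ValueError(f"library {lib}: copy numbers must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted transcripts, plans, copy numbers and error parameters."""

    transcripts: list[TranscriptModel]
    plans: dict[str, MotifPlan | None]
    expected: dict[str, dict]
    copy_numbers: dict[str, dict[str, int]]
    error_rate: float
    quality_model: QualityModel
    rng_seed: int
    actin_id: str | None

    def transcript(self, gene: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.id == gene:
                return t
        raise KeyError(gene)

    @property
    def gene_ids(self) -> list[str]:
        return [t.id for t in self.transcripts]


# ---------------------------------------------------------------------------
# Construction helpers

def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Random UTR with every ATG broken, so it can never seed a longer ORF."""
    chars = [_BASES[i] for i in rng.integers(0, 4, size=length)]
    s = "".join(chars)
    while "ATG" in s:
        s = s.replace("ATG", "ACG", 1)
    return s


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _mutate_segments(segments: list[tuple[str, str]], divergence: float,
                     rng: np.random.Generator) -> str:
    out = []
    for name, seq in segments:
        if name in scaffold.MUTABLE_SEGMENTS and divergence > 0:
            chars = list(seq)
            start = 1 if name == "signal" else 0  # keep the initiator Met
            for i in range(start, len(chars)):
                if rng.random() < divergence:
                    choices = [c for c in scaffold.MUTABLE_ALPHABET
                               if c != chars[i]]
                    chars[i] = choices[rng.integers(0, len(choices))]
            seq = "".join(chars)
        out.append(seq)
    return "".join(out)


def _expected_report(gene: str, plan: MotifPlan) -> dict:
    """Planted report fields implied by a motif plan (rule functions shared
    with the annotator; what is being tested downstream is recovery from
    sequence, not the rules themselves)."""
    if plan.tm_count == 0:
        return {
            "cys_loop_gap": plan.cys_loop_gap,
            "vicinal_cc_loop_c": plan.vicinal_cc,
            "second_cys_loop": plan.second_cys_loop,
            "tm_count": 0,
            "class_call": "AChBP_like",
            "par_motif": False,
            "selectivity": None,
            "flags": None,
            "tm2_primes": None,
        }
    primes = {**scaffold.LINKER_DEFAULT_PRIMES,
              **{k: v for k, v in scaffold.TM2_DEFAULT_PRIMES.items()
                 if k <= scaffold.PRIME_MAX}}
    for k, res in plan.tm2_prime_residues.items():
        if scaffold.PRIME_MIN <= k <= scaffold.PRIME_MAX:
            primes[k] = res
    selectivity, _ = selectivity_from_primes(primes)
    return {
        "cys_loop_gap": plan.cys_loop_gap,
        "vicinal_cc_loop_c": plan.vicinal_cc,
        "second_cys_loop": plan.second_cys_loop,
        "tm_count": 4,
        "class_call": class_from_features(4, plan.vicinal_cc,
                                                 selectivity),
        "par_motif": par_motif_from_primes(primes),
        "selectivity": selectivity,
        "flags": pharmacology_from_primes(primes, tm3_gly=True,
                                                 tm3_thr=True),
        "tm2_primes": primes,
    }


def random_motif_plan(rng: np.random.Generator) -> MotifPlan:
    """A random plausible motif plan spanning the subunit archetypes:
    rdl-like anion, nACh-like cation, atypical-pore, and AChBP-like."""
    gap = int(rng.choice([12, 13, 14, 16]))
    second = bool(rng.random() < 0.3)
    vicinal = bool(rng.random() < 0.3)
    if rng.random() < 0.15:
        return MotifPlan(cys_loop_gap=gap, second_cys_loop=second,
                         vicinal_cc=vicinal, tm_count=0)
    overrides: dict[int, str] = {}
    archetype = rng.random()
    if archetype < 0.45:
        pass                                       # rdl-like anion defaults
    elif archetype < 0.75:
        overrides.update({-2: "S", -1: "E", 0: "Q", 13: "V", 20: "E"})
    else:
        overrides.update({-1: "K", 20: "S"})       # atypical pore
    if rng.random() < 0.3:
        overrides[2] = "S"      # dieldrin-resistance mutation
    if rng.random() < 0.3:
        overrides[6] = "A"
    if rng.random() < 0.3:
        overrides[9] = "V"
    if rng.random() < 0.2:
        overrides.setdefault(-2, "S")
    if rng.random() < 0.1:
        overrides[0] = "K"      # basic but non-canonical 0'
    return MotifPlan(cys_loop_gap=gap, second_cys_loop=second,
                     vicinal_cc=vicinal, tm2_prime_residues=overrides)


def _segment_offsets(segments: list[tuple[str, str]]) -> dict[str, tuple[int, int]]:
    offsets = {}
    pos = 0
    for name, seq in segments:
        offsets[name] = (pos, pos + len(seq))
        pos += len(seq)
    return offsets


def make_synthetic_transcriptome(spec: TranscriptomeSpec) -> SyntheticTruth:
    """Build a deterministic ground-truth transcriptome from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    transcripts: list[TranscriptModel] = []
    plans: dict[str, MotifPlan | None] = {}
    expected: dict[str, dict] = {}
    for gene in spec.gene_ids():
        plan = spec.motif_plan.get(gene)
        if plan is not None:
            segments = scaffold.build_segments(
                plan.cys_loop_gap, plan.vicinal_cc, plan.second_cys_loop,
                plan.tm_count, plan.tm2_prime_residues)
            protein = _mutate_segments(segments, spec.divergence, rng)
            polya_len = plan.polya_length
            expected[gene] = _expected_report(gene, plan)
            expected[gene]["regions"] = _segment_offsets(segments)
        else:
            lo, hi = spec.gene_length_range
            orf_nt = int(rng.integers(lo, hi + 1)) // 3 * 3
            n_res = orf_nt // 3 - 2
            alphabet = scaffold.MUTABLE_ALPHABET
            protein = "M" + "".join(
                alphabet[i] for i in rng.integers(0, len(alphabet),
                                                  size=n_res))
            polya_len = spec.generic_polya_length
        for _attempt in range(5):
            utr5 = _random_utr(rng, int(rng.integers(*spec.utr5_range)))
            utr3 = _random_utr(rng, int(rng.integers(*spec.utr3_range)))
            cds = _backtranslate(protein, rng)
            seq = utr5 + cds + utr3 + "A" * polya_len
            morf = (len(utr5), len(utr5) + len(cds))
            found = find_morf(seq, id=gene, min_codons=min(50, len(protein)))
            if found.morf == morf and found.strand == "+":
                break
        else:  # pragma: no cover - vanishingly unlikely with no-ATG UTRs
            raise RuntimeError(f"{gene}: could not plant an unambiguous mORF")
        model = TranscriptModel(id=gene, seq=seq, morf=morf, strand="+",
                                protein=protein, polya=detect_polya(seq))
        transcripts.append(model)
        plans[gene] = plan
    copy_numbers = spec.copy_numbers
    if copy_numbers is None:
        copy_numbers = {}
        for lib in spec.libraries:
            per_gene = {g: int(rng.integers(1, 21)) for g in spec.gene_ids()}
            if spec.include_actin:
                per_gene["actin"] = 50
            copy_numbers[lib] = per_gene
    return SyntheticTruth(
        transcripts=transcripts, plans=plans, expected=expected,
        copy_numbers={lib: dict(cn) for lib, cn in copy_numbers.items()},
        error_rate=spec.error_rate, quality_model=spec.quality_model,
        rng_seed=spec.rng_seed,
        actin_id="actin" if spec.include_actin else None)


# ---------------------------------------------------------------------------
# Read simulation

_BASE_IDX = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_IDX[ord(_b)] = _i
_IDX_BASE = np.frombuffer("ACGT".encode(), dtype=np.uint8)
del _i, _b


def _apply_errors(mat: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Uniform substitutions on an ASCII uint8 matrix of reads."""
    if error_rate <= 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    n = int(mask.sum())
    if n:
        idx = _BASE_IDX[mat[mask]]
        mat[mask] = _IDX_BASE[(idx + rng.integers(1, 4, size=n)) % 4]
    return mat


def _sample_quals(n_reads: int, read_len: int, qm: QualityModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Integer Phred matrix from the two-state Markov model."""
    low = np.zeros((n_reads, read_len), dtype=bool)
    if qm.tail_prob > 0:
        state = rng.random(n_reads) < qm.tail_prob
        low[:, 0] = state
        for j in range(1, read_len):
            u = rng.random(n_reads)
            state = np.where(state, u >= qm.recovery_prob, u < qm.tail_prob)
            low[:, j] = state
    means = np.where(low, qm.low_q, qm.high_q)
    quals = rng.normal(means, qm.q_sd)
    return np.clip(np.rint(quals), 2, 41).astype(np.int64)


def simulate_reads(truth: SyntheticTruth, library: str, n_pairs: int,
                   read_length: int = 100, rng_seed: int = 0,
                   insert_mean: float = 250.0,
                   insert_sd: float = 30.0) -> list[QualityRead]:
    """Simulate paired-end reads for one library.

    Pair counts per gene are multinomial with weights
    copy_number x (transcript_length - read_length + 1); fragments are
    uniform within the transcript and sequenced from either strand.
    Returns reads interleaved R1, R2.
    """
    if library not in truth.copy_numbers:
        raise KeyError(f"unknown library {library!r}; "
                       f"have {sorted(truth.copy_numbers)}")
    shortest = min(len(t.seq) for t in truth.transcripts)
    if read_length > shortest:
        raise ValueError(f"read_length {read_length} exceeds shortest "
                         f"transcript ({shortest} nt)")
    rng = np.random.default_rng(rng_seed)
    copies = truth.copy_numbers[library]
    genes = truth.gene_ids
    weights = np.array(
        [copies[g] * (len(truth.transcript(g).seq) - read_length + 1)
         for g in genes], dtype=float)
    counts = rng.multinomial(n_pairs, weights / weights.sum())
    qm = truth.quality_model
    reads: list[QualityRead] = []
    pair_no = 0
    for gene, n_gene in zip(genes, counts):
        if n_gene == 0:
            continue
        seq = truth.transcript(gene).seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = len(seq)
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n_gene)),
            read_length, L).astype(np.int64)
        starts = rng.integers(0, L - inserts + 1)
        ends = starts + inserts
        minus = rng.random(n_gene) < 0.5
        offsets = np.arange(read_length)
        fwd = arr[starts[:, None] + offsets]            # fragment 5' end
        rev_raw = arr[(ends - read_length)[:, None] + offsets]
        # reverse-complement the fragment 3' read
        comp = np.zeros(128, dtype=np.uint8)
        for a, b in zip(b"ACGT", b"TGCA"):
            comp[a] = b
        rev = comp[rev_raw[:, ::-1]]
        # plus-orientation fragments: R1 reads the 5' end forward, R2 the 3'
        # end reverse-complemented; minus-orientation fragments swap roles
        r1 = np.where(minus[:, None], rev, fwd)
        r2 = np.where(minus[:, None], fwd, rev)
        r1 = _apply_errors(r1, truth.error_rate, rng)
        r2 = _apply_errors(r2, truth.error_rate, rng)
        q1 = _sample_quals(n_gene, read_length, qm, rng)
        q2 = _sample_quals(n_gene, read_length, qm, rng)
        for i in range(n_gene):
            rid = f"{library}.{pair_no:07d}.{gene}"
            reads.append(QualityRead(id=rid, mate=1,
                                     seq=r1[i].tobytes().decode(),
                                     qual=q1[i].tolist()))
            reads.append(QualityRead(id=rid, mate=2,
                                     seq=r2[i].tobytes().decode(),
                                     qual=q2[i].tolist()))
            pair_no += 1
    return reads


def tile_reads(seq: str, read_length: int = 100, stride: int = 2,
               quality: int = 38, id_prefix: str = "tile",
               alternate_strands: bool = True) -> list[QualityRead]:
    """Error-free reads tiling a sequence flush with both ends.

    Start positions run 0, stride, 2*stride, ... and always include the
    final position len(seq) - read_length, so assembly can recover both
    transcript ends exactly.
    """
    L = len(seq)
    if read_length > L:
        raise ValueError("read_length exceeds sequence length")
    starts = list(range(0, L - read_length + 1, stride))
    if starts[-1] != L - read_length:
        starts.append(L - read_length)
    reads = []
    for n, s in enumerate(starts):
        sub = seq[s:s + read_length]
        if alternate_strands and n % 2:
            sub = revcomp(sub)
        reads.append(QualityRead(id=f"{id_prefix}.{n:05d}", mate=0, seq=sub,
                                 qual=[quality] * read_length))
    return reads


# ---------------------------------------------------------------------------
# Persistence

def write_truth(truth: SyntheticTruth, directory: str | Path,
                reads_by_library: dict[str, list[QualityRead]] | None = None
                ) -> dict[str, Path]:
    """Write transcripts (FASTA), truth table (TSV), scalars/plans (JSON)
    and optional reads (gzipped FASTQ, /1 /2 suffixes).  Round-trips
    through read_truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["transcripts"] = directory / "transcripts.fasta"
    write_fasta([(t.id, t.seq) for t in truth.transcripts],
                paths["transcripts"])
    rows = ["\t".join([
        "gene", "length", "morf_start", "morf_end", "strand",
        "polya_start", "polya_end", "cys_loop_gap", "vicinal_cc",
        "second_cys_loop", "tm_count"])]
    for t in truth.transcripts:
        plan = truth.plans.get(t.id)
        polya = t.polya or ("", "")
        rows.append("\t".join(str(x) for x in [
            t.id, len(t.seq), t.morf[0], t.morf[1], t.strand,
            polya[0], polya[1],
            plan.cys_loop_gap if plan else "",
            plan.vicinal_cc if plan else "",
            plan.second_cys_loop if plan else "",
            plan.tm_count if plan else ""]))
    paths["table"] = directory / "truth.tsv"
    paths["table"].write_text("\n".join(rows) + "\n")
    meta = {
        "rng_seed": truth.rng_seed,
        "error_rate": truth.error_rate,
        "quality_model": asdict(truth.quality_model),
        "copy_numbers": truth.copy_numbers,
        "actin_id": truth.actin_id,
        "plans": {g: (None if p is None else
                      {**asdict(p),
                       "tm2_prime_residues": {str(k): v for k, v in
                                              p.tm2_prime_residues.items()}})
                  for g, p in truth.plans.items()},
        "expected": {g: {**e, "tm2_primes": None if e["tm2_primes"] is None
                         else {str(k): v for k, v in e["tm2_primes"].items()}}
                     for g, e in truth.expected.items()},
    }
    paths["meta"] = directory / "truth.json"
    paths["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
    if reads_by_library:
        for lib, reads in reads_by_library.items():
            for mate in (1, 2):
                p = directory / f"{lib}_R{mate}.fastq.gz"
                write_fastq((r for r in reads if r.mate == mate), p)
                paths[f"{lib}_R{mate}"] = p
    return paths


def read_truth(directory: str | Path) -> SyntheticTruth:
    directory = Path(directory)
    meta = json.loads((directory / "truth.json").read_text())
    table: dict[str, dict] = {}
    lines = (directory / "truth.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        table[rec["gene"]] = rec
    plans = {}
    for g, p in meta["plans"].items():
        if p is None:
            plans[g] = None
        else:
            p = dict(p)
            p["tm2_prime_residues"] = {int(k): v for k, v in
                                       p["tm2_prime_residues"].items()}
            p["cys_loop_gap"] = int(p["cys_loop_gap"])
            plans[g] = MotifPlan(**p)
    expected = {}
    for g, e in meta["expected"].items():
        e = dict(e)
        if e["tm2_primes"] is not None:
            e["tm2_primes"] = {int(k): v for k, v in e["tm2_primes"].items()}
        expected[g] = e
    transcripts = []
    for gene, seq in read_fasta(directory / "transcripts.fasta"):
        rec = table[gene]
        morf = (int(rec["morf_start"]), int(rec["morf_end"]))
        from Bio.Seq import Seq
        protein = str(Seq(seq[morf[0]:morf[1] - 3]).translate())
        polya = None
        if rec["polya_start"]:
            polya = (int(rec["polya_start"]), int(rec["polya_end"]))
        transcripts.append(TranscriptModel(
            id=gene, seq=seq, morf=morf, strand=rec["strand"],
            protein=protein, polya=polya))
    return SyntheticTruth(
        transcripts=transcripts, plans=plans, expected=expected,
        copy_numbers=meta["copy_numbers"], error_rate=meta["error_rate"],
        quality_model=QualityModel(**meta["quality_model"]),
        rng_seed=meta["rng_seed"], actin_id=meta["actin_id"])
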