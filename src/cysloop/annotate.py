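"""Rule-based Cys-loop subunit characterization.

A query protein is anchored to the bundled reference profile by global
pairwise alignment (end gaps free, BLOSUM62) and region boundaries are
transferred through the alignment.  On top of the anchored regions the
module applies the field's classification rules:

* Cys-loop span: residues strictly between the two signature cysteines
  (13 in canonical subunits, more in atypical ones such as AChBP).
* Vicinal Loop-C cysteines: the adjacent CC pair diagnostic of nACh
  alpha subunits; a second, non-adjacent Loop-C cysteine pair marks the
  extra beta9-beta10 disulfide of GluCl/HisCl/pHCl-type subunits.
* TM2 prime numbering: 0' is anchored to the conserved TM1-TM2 linker
  arginine column; indices run contiguously -2'..20'.
* Ion selectivity: basic 0' (R strictly; K accepted with a warning) with a
  non-acidic -1' predicts an anion channel; acidic -1' (or 20') predicts a
  cation channel; conflicting evidence (e.g. basic -1') is atypical.
* Pharmacology: dieldrin site = A2'+T6'+L9'; picrotoxin site = P-2'+A2';
  fipronil site = dieldrin site plus the anchored TM3 threonine;
  ivermectin site = the anchored TM3 glycine, with support-column matches
  reported as evidence counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from Bio import Align
from Bio.Align import substitution_matrices

from . import scaffold
from .scaffold import ReferenceProfile, default_profile

ACIDIC = "ED"
BASIC = "KR"


class AnchorError(ValueError):
    """Query could not be anchored to the reference profile."""


@dataclass
class RegionMap:
    """Query-coordinate intervals for the reference regions.

    ``mapping`` carries the full reference->query position map for anchored
    columns; ``coverage`` the aligned fraction of each reference region.
    """

    intervals: dict[str, tuple[int, int]]
    coverage: dict[str, float]
    mapping: dict[int, int]
    score: float
    profile_name: str

    def tm_count(self, min_coverage: float = 0.5) -> int:
        return sum(1 for tm in scaffold.TM_REGIONS
                   if self.coverage.get(tm, 0.0) >= min_coverage)


@dataclass
class PrimeMap:
    """TM2 prime numbering: prime index -> (residue, absolute position)."""

    positions: dict[int, tuple[str, int]]
    anchor_rule: str = "linker arginine column"

    def residue(self, k: int) -> str | None:
        entry = self.positions.get(k)
        return entry[0] if entry else None

    def residues(self) -> dict[int, str]:
        return {k: v[0] for k, v in self.positions.items()}


@dataclass
class MotifReport:
    id: str
    cys_loop_gap: int | None = None
    second_cys_loop: bool = False
    vicinal_cc_loop_c: bool = False
    tm_count: int = 0
    class_call: str = "ambiguous"
    par_motif: bool = False
    selectivity: str | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    evidence: dict[str, str] = field(default_factory=dict)
    ivermectin_support: int = 0
    anchor_score: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "MotifReport":
        return cls(**d)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # older attribute spelling
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def anchor_regions(protein: str, profile: ReferenceProfile | None = None,
                   min_score_frac: float = 0.2) -> RegionMap:
    """Anchor a query protein to the reference profile by alignment transfer.

    Raises AnchorError when the alignment score falls below
    ``min_score_frac`` of the reference self-score.
    """
    profile = profile or default_profile()
    if len(protein) < 60:
        raise AnchorError(f"query too short to anchor ({len(protein)} aa)")
    aligner = _make_aligner()
    self_score = aligner.score(profile.sequence, profile.sequence)
    alignment = aligner.align(profile.sequence, protein)[0]
    if alignment.score < min_score_frac * self_score:
        raise AnchorError(
            f"anchoring score {alignment.score:.0f} below floor "
            f"{min_score_frac * self_score:.0f}")
    mapping: dict[int, int] = {}
    for (tstart, tend), (qstart, qend) in zip(*alignment.aligned):
        for off in range(tend - tstart):
            mapping[tstart + off] = qstart + off
    intervals: dict[str, tuple[int, int]] = {}
    coverage: dict[str, float] = {}
    for name, (rstart, rend) in profile.regions.items():
        qpos = [mapping[p] for p in range(rstart, rend) if p in mapping]
        coverage[name] = len(qpos) / (rend - rstart)
        if qpos:
            intervals[name] = (min(qpos), max(qpos) + 1)
    return RegionMap(intervals=intervals, coverage=coverage, mapping=mapping,
                     score=alignment.score, profile_name=profile.name)


# ---------------------------------------------------------------------------
# Extracellular features

def _loop_c_cys_positions(protein: str, regions: RegionMap,
                          pad: int = 1) -> list[int]:
    if "loop_C" not in regions.intervals:
        return []
    start, end = regions.intervals["loop_C"]
    start = max(0, start - pad)
    end = min(len(protein), end + pad)
    return [i for i in range(start, end) if protein[i] == "C"]


def cys_loop_span(protein: str, regions: RegionMap) -> int | None:
    """Residue count strictly between the two Cys-loop cysteines, or None."""
    if "cys_loop" not in regions.intervals:
        return None
    start, end = regions.intervals["cys_loop"]
    start = max(0, start - 2)
    end = min(len(protein), end + 2)
    cys = [i for i in range(start, end) if protein[i] == "C"]
    if len(cys) < 2:
        return None
    return cys[-1] - cys[0] - 1


def has_vicinal_cc(protein: str, regions: RegionMap) -> bool:
    cys = _loop_c_cys_positions(protein, regions)
    return any(b - a == 1 for a, b in zip(cys, cys[1:]))


def has_second_cys_loop(protein: str, regions: RegionMap) -> bool:
    """A non-adjacent cysteine pair in Loop C beyond any vicinal CC."""
    cys = _loop_c_cys_positions(protein, regions)
    for a, b in zip(cys, cys[1:]):
        if b - a == 1:
            cys = [c for c in cys if c not in (a, b)]
            break
    return len(cys) >= 2


# ---------------------------------------------------------------------------
# TM2 prime numbering and rules on it

def prime_numbering(protein: str, regions: RegionMap) -> PrimeMap:
    """Assign -2'..20' contiguously from the anchored 0' linker column."""
    pos0 = regions.mapping.get(scaffold.PRIME0_POS)
    if pos0 is None:
        raise AnchorError("0' anchor column is gapped in the query")
    positions: dict[int, tuple[str, int]] = {}
    for k in range(scaffold.PRIME_MIN, scaffold.PRIME_MAX + 1):
        p = pos0 + k
        if 0 <= p < len(protein):
            positions[k] = (protein[p], p)
    if 0 not in positions:
        raise AnchorError("0' position falls outside the query")
    return PrimeMap(positions=positions)


def selectivity_from_primes(residues: dict[int, str]) -> tuple[str, list[str]]:
    """Pure selectivity rule on prime-position residues.

    Returns (selectivity, warnings).
    """
    warnings: list[str] = []
    r_m1 = residues.get(-1)
    r_0 = residues.get(0)
    r_20 = residues.get(20)
    if r_m1 in tuple(ACIDIC):
        return "cation", warnings
    if r_m1 in tuple(BASIC):
        return "atypical", warnings
    if r_0 in tuple(BASIC):
        if r_0 == "K":
            warnings.append("basic 0' is lysine, not the canonical arginine")
        return "anion", warnings
    if r_20 in tuple(ACIDIC):
        return "cation", warnings
    return "atypical", warnings


def classify_selectivity(prime_map: PrimeMap) -> str:
    return selectivity_from_primes(prime_map.residues())[0]


def par_motif_from_primes(residues: dict[int, str]) -> bool:
    return (residues.get(-2), residues.get(-1), residues.get(0)) == ("P", "A", "R")


def pharmacology_from_primes(residues: dict[int, str], tm3_gly: bool,
                             tm3_thr: bool) -> dict[str, bool]:
    dieldrin = (residues.get(2) == "A" and residues.get(6) == "T"
                and residues.get(9) == "L")
    return {
        "dieldrin_site": dieldrin,
        "fipronil_site": dieldrin and tm3_thr,
        "picrotoxin_site": residues.get(-2) == "P" and residues.get(2) == "A",
        "ivermectin_site": tm3_gly,
    }


def tm3_columns(protein: str, regions: RegionMap) -> tuple[bool, bool, int]:
    """(glycine at the TM3 ivermectin column, threonine at the TM3 fipronil
    column, ivermectin support-column match count)."""
    gpos = regions.mapping.get(scaffold.TM3_G_POS)
    tpos = regions.mapping.get(scaffold.TM3_T_POS)
    gly = gpos is not None and protein[gpos] == "G"
    thr = tpos is not None and protein[tpos] == "T"
    support = 0
    for refpos in scaffold.IVERMECTIN_SUPPORT_POS:
        qpos = regions.mapping.get(refpos)
        if qpos is not None and protein[qpos] == scaffold.REFERENCE_SEQ[refpos]:
            support += 1
    return gly, thr, support


def pharmacology_flags(prime_map: PrimeMap, regions: RegionMap,
                       protein: str) -> dict[str, bool]:
    gly, thr, _ = tm3_columns(protein, regions)
    return pharmacology_from_primes(prime_map.residues(), gly, thr)


# ---------------------------------------------------------------------------
# Classification

def class_from_features(tm_count: int, vicinal_cc: bool,
                        selectivity: str | None) -> str:
    """Total rule table mapping features to a single class call."""
    if tm_count == 0:
        return "AChBP_like"
    if selectivity == "cation":
        if tm_count == 4:
            return "alpha_nACh" if vicinal_cc else "non_alpha_nACh"
        return "cation_subunit"
    if selectivity == "anion":
        return "anion_subunit"
    return "ambiguous"


def classify_subunit(protein: str, regions: RegionMap,
                     prime_map: PrimeMap | None = None) -> str:
    tm_count = regions.tm_count()
    if tm_count == 0:
        return "AChBP_like"
    if prime_map is None:
        try:
            prime_map = prime_numbering(protein, regions)
        except AnchorError:
            return "ambiguous"
    selectivity = classify_selectivity(prime_map)
    return class_from_features(tm_count, has_vicinal_cc(protein, regions),
                               selectivity)


# ---------------------------------------------------------------------------
# Composite

def annotate(protein: str, profile: ReferenceProfile | None = None,
             id: str = "protein") -> MotifReport:
    """Full rule-based report for one protein.

    Anchoring failures degrade gracefully to class_call='ambiguous' with the
    diagnostic recorded in warnings.
    """
    protein = protein.upper()
    try:
        regions = anchor_regions(protein, profile)
    except AnchorError as exc:
        return MotifReport(id=id, class_call="ambiguous",
                           warnings=[f"unanchorable: {exc}"])
    report = MotifReport(id=id, anchor_score=regions.score)
    report.cys_loop_gap = cys_loop_span(protein, regions)
    report.vicinal_cc_loop_c = has_vicinal_cc(protein, regions)
    report.second_cys_loop = has_second_cys_loop(protein, regions)
    report.tm_count = regions.tm_count()
    if report.tm_count == 0:
        report.class_call = "AChBP_like"
        return report
    try:
        prime_map = prime_numbering(protein, regions)
    except AnchorError as exc:
        report.class_call = "ambiguous"
        report.warnings.append(str(exc))
        return report
    residues = prime_map.residues()
    report.selectivity, warns = selectivity_from_primes(residues)
    report.warnings.extend(warns)
    report.par_motif = par_motif_from_primes(residues)
    gly, thr, support = tm3_columns(protein, regions)
    report.flags = pharmacology_from_primes(residues, gly, thr)
    report.ivermectin_support = support
    report.class_call = class_from_features(
        report.tm_count, report.vicinal_cc_loop_c, report.selectivity)
    report.evidence = {
        "prime_-2": residues.get(-2, ""),
        "prime_-1": residues.get(-1, ""),
        "prime_0": residues.get(0, ""),
        "prime_2": residues.get(2, ""),
        "prime_6": residues.get(6, ""),
        "prime_9": residues.get(9, ""),
        "prime_13": residues.get(13, ""),
        "prime_20": residues.get(20, ""),
        "tm3_ivermectin_col": "G" if gly else "-",
        "tm3_fipronil_col": "T" if thr else "-",
    }
    return report


def annotate_all(records: list[tuple[str, str]],
                 profile: ReferenceProfile | None = None) -> list[MotifReport]:
    profile = profile or default_profile()
    return [annotate(seq, profile, id=name) for name, seq in records]


def reports_to_frame(reports: list[MotifReport]):
    import pandas as pd

    rows = []
    for r in reports:
        row = r.to_dict()
        row.update({f"flag_{k}": v for k, v in row.pop("flags").items()})
        row.pop("evidence")
        row["warnings"] = "; ".join(row["warnings"])
        rows.append(row)
    return pd.DataFrame(rows)
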