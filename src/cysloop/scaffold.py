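"""Reference subunit scaffold shared by the synthetic generator and the annotator.

Cys-loop ligand-gated ion channel (LGIC) subunits share a stereotyped
architecture: a cleavable signal region, an extracellular ligand-binding
domain carrying loops A-G and the signature disulfide-bonded Cys-loop
(canonically C-x13-C), then four transmembrane helices TM1-TM4.  The short
TM1-TM2 linker holds the -2'/-1'/0' positions of the standard TM2 prime
numbering; TM2 itself lines the channel pore and its prime-position residues
determine ion selectivity and insecticide sensitivity.

This module defines one synthetic reference subunit laid out on that
architecture, with every region's coordinates recorded.  It is a synthetic
stand-in profile, not any real protein: the annotator anchors query proteins
against it by pairwise alignment and transfers region boundaries through the
alignment, and the synthetic generator builds ground-truth proteins on the
same backbone so that planted features are recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

# Residues eligible for background mutation / random fill.  Cysteine is
# excluded everywhere outside planted columns so that stray CC pairs or
# spurious Cys-loop cysteines can never arise by chance; Met is kept out of
# random fill to avoid spurious start codons dominating short ORFs.
MUTABLE_ALPHABET = "ADEFGHIKLNPQRSTVWY"

DEFAULT_CYS_LOOP_GAP = 13

# Gap fillers for the Cys-loop interior at the canonical and variant spans.
# Index = number of residues between the two cysteines.
_CYS_GAP_CORE = "PMDLKNFPMDVQTSTE"  # 16 residues; sliced to the wanted span


def cys_loop_interior(gap: int) -> str:
    """Residues planted between the two Cys-loop cysteines for a given span."""
    if not 8 <= gap <= 16:
        raise ValueError(f"cys_loop_gap {gap} outside supported range 8..16")
    return _CYS_GAP_CORE[:gap]


# Loop C variants.  Positions 4,5 hold the optional vicinal cysteines
# (the nACh-alpha hallmark); positions 1 and 9 hold the optional second
# Cys-loop pair (the beta9-beta10 disulfide of GluCl/HisCl/pHCl subunits).
LOOP_C_BASE = "YDLMSVTLQSET"
LOOP_C_VICINAL_IDX = (4, 5)
LOOP_C_SECOND_IDX = (1, 9)


def loop_c_segment(vicinal_cc: bool, second_cys_loop: bool) -> str:
    seg = list(LOOP_C_BASE)
    if vicinal_cc:
        for i in LOOP_C_VICINAL_IDX:
            seg[i] = "C"
    if second_cys_loop:
        for i in LOOP_C_SECOND_IDX:
            seg[i] = "C"
    return "".join(seg)


# TM2 written as prime positions 1'..23'; the TM1-TM2 linker ends with the
# -2'/-1'/0' triplet (PAR in anion-selective subunits).  Defaults are the
# rdl-like anion channel residues: A2', T6', L9', T13'.
TM2_DEFAULT_PRIMES = {
    1: "V", 2: "A", 3: "L", 4: "G", 5: "I", 6: "T", 7: "T", 8: "V",
    9: "L", 10: "T", 11: "M", 12: "T", 13: "T", 14: "L", 15: "S",
    16: "I", 17: "S", 18: "A", 19: "R", 20: "S", 21: "V", 22: "P", 23: "K",
}
LINKER_DEFAULT_PRIMES = {-2: "P", -1: "A", 0: "R"}
PRIME_MIN, PRIME_MAX = -2, 20

# TM3 anchored columns: the ivermectin-essential glycine and the
# fipronil-associated threonine, as offsets within the TM3 segment.
TM3_IVERMECTIN_G_IDX = 6
TM3_FIPRONIL_T_IDX = 10

_SEGMENTS = [
    ("signal",    "MRSLLVLSVLLALAVQAHSA"),
    ("nterm",     "DNITQPVRVNIS"),
    ("loop_G",    "WIDHRLSW"),
    ("seg1",      "NASEYDGIDE"),
    ("loop_D",    "YTLTLYFQ"),
    ("seg2",      "QVWKPDIFFV"),
    ("loop_A",    "NGKTSYLH"),
    ("seg3",      "MTTPNKLFRI"),
    ("loop_E",    "TPDGTVLY"),
    ("seg4",      "SIRLTITAES"),
    ("cys_loop",  "C" + cys_loop_interior(DEFAULT_CYS_LOOP_GAP) + "C"),
    ("seg5",      "STEVVKTT"),
    ("loop_B",    "SGDYVVMT"),
    ("seg6",      "VYFHLRRH"),
    ("loop_F",    "EDNSANKTWR"),
    ("seg7",      "LIDKLELP"),
    ("loop_C",    LOOP_C_BASE),
    ("pre_tm1",   "EGRVPLLG"),
    ("tm1",       "ILSWVSFWINMDSAGLTLVI"),
    ("linker",    "SQT" + "PAR"),
    ("tm2",       "".join(TM2_DEFAULT_PRIMES[k] for k in range(1, 24))),
    ("tm2_tm3",   "VEADTRES"),
    ("tm3",       "IFVFSAGLTFTALMEYAFLN"),
    ("intra",     "KDAHEKRLDALSRSPSRHHQEMEASLNLRRKELGDLESNK"),
    ("tm4",       "VLDRLSRIAFPLLFGIFNLV"),
    ("cterm",     "YWSRFE"),
]

# Segments dropped for an AChBP-like (soluble, TM-less) protein.
_TM_SEGMENTS = {"pre_tm1", "tm1", "linker", "tm2", "tm2_tm3", "tm3",
                "intra", "tm4"}
ACHBP_TAIL = "GSDE"

REFERENCE_SEQ = "".join(seq for _, seq in _SEGMENTS)

REGIONS: dict[str, tuple[int, int]] = {}
_pos = 0
for _name, _seq in _SEGMENTS:
    REGIONS[_name] = (_pos, _pos + len(_seq))
    _pos += len(_seq)
del _pos, _name, _seq

TM_REGIONS = ("tm1", "tm2", "tm3", "tm4")
LOOP_REGIONS = ("loop_A", "loop_B", "loop_C", "loop_D", "loop_E",
                "loop_F", "loop_G")

#: Absolute reference positions of the two Cys-loop cysteines.
CYS1_POS = REGIONS["cys_loop"][0]
CYS2_POS = REGIONS["cys_loop"][1] - 1

#: Absolute reference position of the 0' anchor (the conserved TM1-TM2
#: linker arginine column).
PRIME0_POS = REGIONS["linker"][1] - 1

#: Absolute reference positions of the TM3 pharmacology columns.
TM3_G_POS = REGIONS["tm3"][0] + TM3_IVERMECTIN_G_IDX
TM3_T_POS = REGIONS["tm3"][0] + TM3_FIPRONIL_T_IDX

#: Columns whose residues contribute supporting evidence for ivermectin
#: contact (hydrogen-bond / van-der-Waals style support counts).  Synthetic
#: stand-in columns spread over TM1-TM3, expressed as absolute positions.
IVERMECTIN_SUPPORT_POS = (
    REGIONS["tm1"][0] + 3,
    REGIONS["tm1"][0] + 12,
    REGIONS["tm2"][0] + 14,   # 15'
    REGIONS["tm3"][0] + 2,
    REGIONS["tm3"][0] + 13,
)

#: Positions that the generator must never touch with background mutations:
#: every planted-feature or anchor column plus the initiator Met.
_FIXED: set[int] = {0, CYS1_POS, CYS2_POS, PRIME0_POS, TM3_G_POS, TM3_T_POS}
_FIXED.update(range(*REGIONS["cys_loop"]))
_FIXED.update(range(*REGIONS["loop_C"]))
_FIXED.update(range(*REGIONS["linker"]))
_FIXED.update(range(*REGIONS["tm2"]))
_FIXED.update(range(*REGIONS["tm3"]))
_FIXED.update(IVERMECTIN_SUPPORT_POS)
FIXED_POSITIONS = frozenset(_FIXED)
del _FIXED


@dataclass(frozen=True)
class ReferenceProfile:
    """The bundled anchoring profile: one reference row plus its region map."""

    name: str
    sequence: str
    regions: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.sequence)


def default_profile() -> ReferenceProfile:
    return ReferenceProfile(
        name="cysloop_ref_synthetic",
        sequence=REFERENCE_SEQ,
        regions=dict(REGIONS),
    )


#: Segments the generator may hit with background mutations.  Everything
#: carrying planted-feature or anchor columns (Cys-loop, loop C, the TM1-TM3
#: block with its prime positions and pharmacology columns) stays fixed so
#: planted features remain recoverable by construction.
MUTABLE_SEGMENTS = frozenset(
    name for name, _ in _SEGMENTS
    if name not in _TM_SEGMENTS | {"cys_loop", "loop_C", "tm4"})


def build_segments(
    cys_loop_gap: int = DEFAULT_CYS_LOOP_GAP,
    vicinal_cc: bool = False,
    second_cys_loop: bool = False,
    tm_count: int = 4,
    tm2_prime_residues: dict[int, str] | None = None,
) -> list[tuple[str, str]]:
    """Per-segment assembly of a protein with planted features.

    ``tm2_prime_residues`` overrides individual prime positions (-2'..23');
    with ``tm_count=0`` the protein is truncated after loop C (AChBP-like).
    """
    overrides = dict(tm2_prime_residues or {})
    parts: list[tuple[str, str]] = []
    for name, seq in _SEGMENTS:
        if tm_count == 0 and name in _TM_SEGMENTS:
            continue
        if name == "cys_loop":
            seq = "C" + cys_loop_interior(cys_loop_gap) + "C"
        elif name == "loop_C":
            seq = loop_c_segment(vicinal_cc, second_cys_loop)
        elif name == "linker":
            chars = list(seq)
            for k in (-2, -1, 0):
                if k in overrides:
                    chars[len(chars) - 3 + (k + 2)] = overrides[k]
            seq = "".join(chars)
        elif name == "tm2":
            chars = list(seq)
            for k, res in overrides.items():
                if 1 <= k <= 23:
                    chars[k - 1] = res
            seq = "".join(chars)
        elif name == "cterm" and tm_count == 0:
            seq = ACHBP_TAIL
        parts.append((name, seq))
    return parts


def build_protein(
    cys_loop_gap: int = DEFAULT_CYS_LOOP_GAP,
    vicinal_cc: bool = False,
    second_cys_loop: bool = False,
    tm_count: int = 4,
    tm2_prime_residues: dict[int, str] | None = None,
) -> str:
    """Assembled protein string; see build_segments."""
    return "".join(seq for _, seq in build_segments(
        cys_loop_gap, vicinal_cc, second_cys_loop, tm_count,
        tm2_prime_residues))
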