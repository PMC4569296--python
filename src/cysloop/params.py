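"""Pipeline-wide tunable parameters.

Every constant of the method lives here: the grooming rule (at least
``min_run`` contiguous bases at Phred >= ``min_q``), the adaptive walking
overlaps (start at 60 nt, escalate by 10 to 90 to kill ambiguity, relax by
10 to 40 when nothing overlaps), the 90-identities-in-100 read-counting
rule, and the substitution matrix used for low-stringency bait searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

_BLOSUM_NAMES = ("BLOSUM45", "BLOSUM62", "BLOSUM80")


@dataclass
class PipelineParams:
    min_run: int = 80          # nt: shortest acceptable high-quality run
    min_q: int = 20            # Phred: score > 19 qualifies
    overlap_init: int = 60     # nt: starting minimum overlap for walking
    overlap_max: int = 90      # nt: escalation ceiling
    overlap_min: int = 40      # nt: relaxation floor
    overlap_step: int = 10     # nt: escalation/relaxation increment
    count_window: int = 100    # nt: denominator of the identity rule
    count_min_ident: int = 90  # identities required per count_window
    blosum_name: str = "BLOSUM62"
    bait_score_threshold: float = 60.0  # substitution-matrix sum
    stop_margin: int = 30      # nt required beyond the STOP codon
    min_orf_codons: int = 50   # codons (incl. start, excl. stop)
    polya_min_len: int = 15    # nt
    polya_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not (self.overlap_min <= self.overlap_init <= self.overlap_max):
            raise ValueError(
                "need overlap_min <= overlap_init <= overlap_max, got "
                f"{self.overlap_min}/{self.overlap_init}/{self.overlap_max}")
        if self.overlap_step <= 0:
            raise ValueError("overlap_step must be positive")
        if (self.overlap_max - self.overlap_init) % self.overlap_step or \
           (self.overlap_init - self.overlap_min) % self.overlap_step:
            raise ValueError("overlap_step must divide both escalation and "
                             "relaxation ranges")
        if not 0 < self.count_min_ident <= self.count_window:
            raise ValueError("count_min_ident must be in (0, count_window]")
        if self.blosum_name not in _BLOSUM_NAMES:
            raise ValueError(f"unknown matrix {self.blosum_name!r}; "
                             f"expected one of {_BLOSUM_NAMES}")
        if self.min_run <= 0 or self.min_q < 0:
            raise ValueError("min_run must be positive and min_q >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


DEFAULT_PARAMS = PipelineParams()
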