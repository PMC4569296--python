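# Methods

This note documents the models, rules and numerical choices behind
`cysloop`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Read grooming

A read is retained only if it contains at least `min_run` (default 80)
contiguous bases with Phred score ≥ `min_q` (default 20, i.e. score
strictly above 19), and it is trimmed to the longest such run (leftmost on
ties, for determinism).  Trimming — rather than pass/fail on the whole
read — maximizes usable overlap material while guaranteeing that every
stored base met the quality bar.  Mates pass or fail independently,
because the walker uses single-read overlaps only.  `N` bases are treated
as Phred 0.  `longest_highq_run` is checked against an exhaustive
per-start scan in the tests.

## Bait search

Groomed reads are translated in six frames, split at stop codons, and
each segment of ≥ 5 residues is scored against the bait by the best
ungapped window under the selected BLOSUM matrix (45/62/80; default 62).
The score is a raw substitution-matrix sum; the default reporting
threshold (60) sits near the self-score of a ~12-residue conserved block,
which is what "low stringency" means operationally here.  Scores are
computed with a vectorized diagonal-sum (`bincount` over anti-diagonals)
and verified against a dictionary-lookup brute force in the tests.

## Transcriptome walking

The contig grows by exact-match overlaps: a candidate read (either
orientation) must match the contig terminus over ≥ the current minimum
overlap and extend beyond it.  Matching is exact (0 mismatches): grooming
removes most errorful bases, and an errorful read simply forms a
singleton pathway that threshold escalation eliminates.  Candidates are
grouped into **pathways** by overhang: a pathway is a distinct maximal
overhang under the prefix partial order, so candidates whose overhang is
a prefix of a longer one support that pathway rather than opening a new
one.  One adaptive step then:

* **1 pathway** — append its longest overhang; reset the threshold to
  `overlap_init` (60 nt).  Escalation/relaxation is per-situation, not
  sticky.
* **> 1 pathway** — raise the threshold by 10 within the same step, up to
  90; if the conflict survives at 90 the walk halts `ambiguous` with all
  pathway overhangs recorded rather than guessing.  If escalation wipes
  out every candidate without isolating one, the walk also reports
  `ambiguous` with the last conflicting pathways.
* **0 pathways** — lower the threshold by 10, down to 40; still nothing
  means `exhausted`.  If relaxation uncovers a conflict instead, the walk
  reports `ambiguous` (raising the threshold again would just return to
  the empty regime).

A 5′ walk is executed as a 3′ walk on the reverse complement, which keeps
overhang-prefix grouping correct in both directions.  3′ walking
continues by default to the poly-A tail (`terminated_polya`); with
`continue_to_polya=False` it stops as soon as the contig holds a complete
forward-strand mORF whose STOP sits at least `stop_margin` (30 nt, so the
STOP is not a truncation artifact) from the contig end
(`terminated_stop`).  Both behaviors are exposed because primary-source
practice varied by gene.  Coordinates are 0-based half-open throughout.

The exact-reconstruction guarantee is tested with reads tiled flush to
both transcript ends (stride 3, ~33× coverage): with random fragment
positions the probability that a read starts exactly at base 0 is small
at any realistic depth, so flush tiling is the right fixture for an
exactness claim; random-fragment simulations are used for the statistical
stages instead.

## mORF, molecular weight, poly-A

The main ORF is the longest ATG-initiated ORF ending in a stop codon
across all six frames (ties: earliest start, then + strand).  There is no
Kozak-context scoring; the standard nuclear genetic code is assumed.
Molecular weights use average (not monoisotopic) residue masses plus one
water, via Biopython, reported in kDa; `X` is rejected.  Poly-A detection
reports the longest terminal run of ≥ 15 A's allowing ≤ 1 non-A,
starting on an A.

## Abundance

A read is scored as derived from a gene when its best ungapped placement
— full read containment, either strand, any offset — reaches
`ceil(90/100 × read length)` identities; the proportional threshold
generalizes the 90-per-100 rule to reads the groomer trimmed below 100
nt.  Counting is exact but seeded: any qualifying placement must contain
an exact aligned k-mer (pigeonhole; k = 8 for 80–100-nt reads), so a
k-mer index proposes offsets and full identity counting verifies them.
The tests cross-check this against the brute-force per-read scorer.
Multi-gene reads count for every gene they match; both strands count
(library strandedness is unknown); matching is ungapped because the rule
is an identical-nucleotide count, not an alignment.  Relative abundance
is (count/mORF length) divided by the same density for actin; actin's own
RA is exactly 1 by definition, and a zero actin count is an error rather
than an infinity.

## Annotation

Region anchoring transfers boundaries from a bundled reference profile
through a global pairwise alignment (BLOSUM62, gap open −11 / extend −1,
end gaps free so truncated or N-terminally extended proteins anchor
cleanly).  A query is `unanchorable` below 20% of the reference
self-score, which cleanly rejects unrelated proteins.  The profile is a
synthetic reference subunit laid out on the canonical architecture
(signal region, loops A–G, Cys-loop, TM1–TM4 with the TM1–TM2 linker and
pore-lining TM2); it is a stand-in built for anchoring, not a real
sequence, and the generator builds its proteins on the same backbone so
planted features are recoverable by construction.

Rules on the anchored protein:

* **Cys-loop span** — residues strictly between the first and last
  cysteine in the anchored Cys-loop window (13 canonically; 14 and 16 in
  atypical subunits); `None` without two cysteines.
* **Vicinal CC** — adjacent cysteines within Loop C only; a remaining
  non-adjacent Loop-C cysteine pair marks the second Cys-loop.
* **Prime numbering** — 0′ is the query position aligned with the
  conserved linker arginine column; indices −2′..20′ are assigned
  contiguously.  A gapped anchor column is an error with a diagnostic.
* **Selectivity** — acidic −1′ ⇒ cation; basic −1′ ⇒ atypical; else
  basic 0′ ⇒ anion (lysine accepted with a warning; arginine is the
  canonical residue); else acidic 20′ ⇒ cation; otherwise atypical.
* **Class call** — a total rule table: no TMs ⇒ AChBP-like; cation with
  4 TMs ⇒ α (vicinal CC) or non-α nACh; anion ⇒ anion subunit; cation
  with partial TMs ⇒ cation subunit; atypical ⇒ ambiguous.  Subunits
  with conflicting pore signatures genuinely cannot be classified by
  sequence rules alone (their archetypes were placed by phylogeny, which
  is out of scope), so `ambiguous` is an explicit class, not a failure.
* **Pharmacology** — boolean sites with contributing residues as
  evidence, not affinity predictions: dieldrin = A2′∧T6′∧L9′;
  picrotoxin = P−2′∧A2′; fipronil = dieldrin ∧ anchored TM3 threonine;
  ivermectin = anchored TM3 glycine, with matches at five support
  columns reported as a count.

## Identity matrices

SDT convention: columns gapped in both rows are excluded; a column gapped
in exactly one row is a scored mismatch.  Display order, when requested,
comes from neighbour joining on 100 − identity with lexicographically
pre-sorted labels for determinism.  The package consumes MSAs; alignment
construction is delegated to an external aligner (the pipeline shells out
to `mafft` when available).

## Synthetic data

The generator emulates the study conditions end to end: transcripts are a
no-ATG 5′ UTR (so the planted mORF is unambiguous), a back-translated CDS
with codons drawn uniformly among synonyms (background residues exclude
cysteine so no spurious Cys pairs can arise), a 3′ UTR, and a poly-A tail
(default 25 nt — long enough to detect, shorter than the 40-nt minimum
overlap so tails cannot bridge genes during walking).  Pair counts per
gene are multinomial with weights copy_number × (length − read_length + 1);
fragments are uniform with a configurable insert (default 250 ± 30 nt)
and sequenced from either strand; errors are uniform substitutions
(default 0.5%; indels are out of scope because overlap matching is
exact).  Qualities come from a two-state Markov chain (high ≈ Q38, low ≈
Q12) whose default tail probability (0.01 per base, recovery 0.25) makes
the grooming rule retain ≈ 52% of 100-nt reads — the retention regime the
method was designed for.

What passing tests show: the implementation honors its contracts — the
grooming rule equals its oracle, walking reconstructs planted transcripts
exactly under error-free flush tilings and reports repeats as ambiguity,
abundance recovers planted copy ratios within multinomial error, the
annotator recovers 100% of planted motif fields.  What they do not show:
robustness to indels, chimeras, paralogous gene families with high
nucleotide identity, expression-dependent biases, or real base-caller
error profiles — none of which the generator emulates.

## Problem sizes

The test suite and the acceptance script run at desk scale as the
package's own verification conditions: 10⁴ random quality vectors for the
grooming oracle, 20 planted truths (~1.1-kb transcripts, ~33× error-free
coverage) for reconstruction, 10⁵ read pairs for abundance recovery, and
50 random planted proteins for annotation recovery.  The original
libraries (hundreds of millions of pairs) differ only in volume, not in
the rules applied.
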