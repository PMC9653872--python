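# Methods

## Scope and model

The package turns a chromosome-scale assembly into a synthesizable
oligo-FISH probe pool with three layered guarantees: every retained oligo
is genome-wide single-copy under an explicit similarity definition; every
selected region carries enough probes per kb to light up in situ; and the
two-color labeling of regions forms a pattern that distinguishes every
chromosome pair. Downstream components predict what the microscope should
show (ideograms, rDNA overlays, signal-pair counts) and how the pool
behaves on related genomes.

## Similarity definition and the uniqueness filter

Off-target similarity between an oligo and a genomic window is **ungapped
positionwise identity over equal-length windows**, taken over all windows
of both strands with the oligo's own origin window (forward strand, same
coordinates) excluded. An oligo is removed when its best off-target
identity strictly exceeds the threshold (default 0.75): at length 50,
38/50 matches removes, 37/50 keeps. This definition was chosen because a
per-window threshold rule needs a window-level statistic, ungapped identity
is the simplest one, and it admits an exact brute-force oracle; gapped
alignment is deliberately out of scope. Including the reverse strand is a
design choice (a probe hybridizes either strand), fixed and tested.

Two engines compute, for every window start, the maximum match count
against any other valid window:

* **exact** — walks every diagonal of the both-strand concatenation
  (`O(G^2)` with `G` the total genome length). Used automatically for
  genomes ≤ 50 kb; its decisions are tested to be identical to an
  independent oracle (per-base indicator matrix products, itself
  cross-checked against a pure-python triple loop).
* **seeded** — enumerates exact shared 12-mers at all offsets between all
  window pairs, then verifies every implicated window pair exhaustively.
  By the pigeonhole argument this is guaranteed for any alignment with at
  most ⌊(50−12)/12⌋ = 3 mismatches (identity ≥ 0.94) and finds a
  near-threshold alignment whenever it contains one exact 12-run. For
  randomly diverged duplications around 90% identity this is effectively
  always; adversarial mismatch spacings can evade it, which is why the
  exact engine is the default at oracle-testable scales and why the seed
  length is configurable. Within huge repeat families the per-k-mer pair
  enumeration is capped at 64 sorted-position lags — ample for planted
  satellite arrays, and irrelevant for candidates because high-copy
  sequence is masked before tiling.

Retained oligos carry their off-target statistic: exact under the exact
engine, a tight lower bound under the seeded engine (below-threshold
values can be under-reported there; the keep/remove decision is what the
engines are built for).

`max_offtarget_identity` on a single oligo is an independent chunked
full-scan (every window compared), usable as a spot check at any scale.

## Repeat pre-masking

High-copy DNA is masked by canonical k-mer frequency: any position covered
by a 17-mer occurring more than 4 times genome-wide is masked (both
parameters configurable; windows containing N never count). This plays the
role a homology-based repeat masker plays in probe-design pipelines —
keeping the tiler out of satellite arrays so the expensive filter sees
plausible candidates — while single-copy correctness rests entirely on the
similarity filter. There is no repeat classification and no consensus
building. Lowercase (soft-masked) input, e.g. from an external masker, is
unioned into the mask by default.

## Region selection

The published design this package generalizes reports one or two regions
per chromosome, 1.40–2.14 Mb, all ≥ 2.71 oligos/kb, but not the selection
algorithm; the procedure here is therefore fixed as the package's own,
deterministic choice:

1. score windows of the range floor (default 1.3 Mb) on a 100-kb grid by
   retained-oligo density; keep those ≥ the floor density (default
   2 oligos/kb, with 1.5/kb retained as the literature's lower reference
   bound);
2. greedily take the densest non-overlapping windows per chromosome, ties
   to the leftmost; when a centromere is given and a second region is
   wanted, qualifying windows on the opposite arm are preferred;
3. extend each pick rightward then leftward in 50-kb steps while density
   stays above the floor, length below the ceiling (2.2 Mb), and regions
   stay disjoint.

Grid and extension steps scale with the region range for scaled-down runs.
Internal primer ids P1..Pn follow chromosome order; densities are reported
at full precision and displayed with half-up rounding to 2 decimals.

## Barcode scheme and in-silico PCR

A chromosome's pattern is its ordered list of `(position fraction, arm,
color)` blocks. Two patterns collide when nothing observable separates
them: same length, same ordered colors, all corresponding positions within
`position_tolerance` (default 0.15 — a free parameter; no numeric
resolvability criterion exists in the cytogenetic literature, so it is
stated and configurable), and same arms wherever both are known; unknown
positions or arms cannot separate. The assigner enumerates external-color
vectors in lexicographic order over sublibraries sorted by (chromosome,
region start) — at most `2^14` for the motivating design — and accepts the
first vector that verifies; failure raises an error listing the
positionally indistinguishable chromosome pairs.

Probes are laid out in standard amplicon orientation,
`external.F ∥ internal.F ∥ insert ∥ rc(internal.R) ∥ rc(external.R)`, and
in-silico PCR is exact substring matching (forward primer present,
reverse-complemented reverse primer downstream). Mismatch tolerance and
3'-end rules are out of scope because generated primer sets are orthogonal
by construction (pairwise distinct, substring-free, GC 0.4–0.6, no
homopolymer > 4); real primer sequences can be supplied as TSV.

## Cross-species transfer

The mapper reports each oligo's best window on the target (both strands,
same identity definition, default floor 0.88 ≈ 6 mismatches in 50), ties
broken to the leftmost window on the lowest-indexed chromosome, forward
strand first. It replaces a spliced aligner because only cluster structure
is consumed downstream; externally produced hit tables can be supplied as
TSV. Per sublibrary: mapped fraction, modal target chromosome, the span of
the central 90% of hit positions, and coherence — the fraction of mapped
oligos on the assigned chromosome within the span dilated by half its
length per side. The dilation exists so that a tight unique-hit cluster
scores exactly 1.0 (an undilated middle-90% span would cap coherence at
0.9 by construction) while paralogous strays and translocations still
count against it. Sublibraries with mapped fraction below 0.1 are excluded
from the transferred barcode, which is then re-verified with arms unknown.

## rDNA patterns, ideograms, karyotype measures

Cytogenetic surveys report rDNA site *classes*, not coordinates, so
positions are canonicalized: terminal = distal 5% of the arm, proximal =
15–25% of the arm out from the centromere, centromeric = centromere ± 5%
of chromosome length (all configurable; arm defaults to the short arm when
unreported). Pattern identity is the deduplicated sorted set of
`(locus, chromosome, class)` per basic genome — ploidy-independent, so a
diploid and a tetraploid sharing sites share a type. Expected metaphase
signal pairs are `sites × ploidy/2`; odd ploidies floor with a warning,
and the known pentaploid case of undetected Chr_4 45S signals is kept as a
per-accession observation note, not a pattern change. The shipped
11-species table resolves into 8 types.

Ideograms place one block per sublibrary at its region's fractional span;
rDNA overlays never move or recolor existing blocks. Relative length is
`100 × (short+long) / Σ complement` per cell, averaged over cells (cells
missing a chromosome are excluded with a warning); arm ratio is
long/short, swapping arms if given reversed.

## Synthetic data

Toy genomes are i.i.d. uniform sequence (GC configurable) with planted,
exactly-recorded structure: tandem satellite arrays (default monomers 102,
149, 159 bp, matching the satellites characterized in true cherries),
near-duplicate segments with an **exact** substitution count
(`round((1−identity)·length)`, so a 50-mer at 0.76 carries exactly 12
mismatches — pinning the filter boundary deterministically), assembly-gap
N runs, and centromeres. The 8-chromosome demonstration genome places one
250-kb clean island per 600-kb chromosome at a chromosome-specific offset,
flanked by N gaps with embedded satellite arrays, plus one 300-bp
duplication at 0.90 identity per island; with the megabase rules scaled by
one tenth, selection lands at distinct positions per chromosome and a
2-color barcode is resolvable.

What the toys do *not* emulate: real base composition and repeat
landscapes, segmental duplication families, gene-family paralogy, assembly
errors, and hybridization chemistry. Passing tests therefore demonstrate
algorithmic correctness under the stated similarity model — not wet-lab
signal strength, nor the oligo yields of a real 200–300-Mb genome, which
are orders of magnitude beyond desk-scale test sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 20 × 5-kb single-record
genomes for oracle equivalence (exact engine; the oracle is the slow
independent path), 4 × 60-kb genomes for mapping/transfer fixtures with
the pool subsampled 1-in-15 per sublibrary, and the 8 × 600-kb demo genome
(seeded engine) for the end-to-end pipeline — sizes chosen so the whole
suite runs in about a minute on one CPU while every rule (boundary
arithmetic included) is exercised at full fidelity. Integer match counts
are used throughout the filter (no floating-point threshold ambiguity:
`keep ⇔ matches ≤ ⌊threshold·L⌋`); densities only become floats at the
region stage; displayed densities use decimal half-up rounding. All
generators take explicit seeds; identical inputs give identical outputs
everywhere, including region boundaries and color vectors.

## Known limitations

* Gapped/spliced homology is invisible to both the filter and the mapper
  by design; an indel-shifted near-duplicate can evade the 75% rule.
* The seeded engine is heuristic between ~76% and ~94% identity
  off-targets (see above); use the exact engine where that matters and is
  affordable.
* Probe thermodynamics (Tm, hairpins, dimers) are not modeled; the
  optional GC-range filter is a practical stand-in.
* Region selection optimizes density greedily, not synthesis cost or
  multi-objective trade-offs.
* One published density value (6568 oligos / 1,594,437 bp printed as 4.11)
  disagrees with count/length arithmetic (4.12); the package defines
  density strictly as count/length and does not imitate the discrepancy.
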