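# Methods

## The cassette model

A cgRNA expression cassette is modelled as an ordered list of *parts*
tiling a DNA sequence (0-based, half-open coordinates). The grammars cover
the variant panel used in cgRNA work: mature `U6+27` guides (scaffold +
spacer behind a Pol III promoter whose transcript carries a 27-nt leader),
unprocessed `Pre` guides (spacer flanked by two scaffold copies), linear and
circular `Sp1` cassettes (ligation sequence, 42-nt 5′ linker region,
optional F30/Broccoli module, scaffold–spacer–scaffold, 41-nt 3′ linker
region, ligation sequence, the circular form flanked by Twister ribozymes),
screened-linker circles (`C-L1…C-L8`: the 42/41-nt regions replaced by
10-nt polyAC cores with 5–7-nt random extensions), `d27` variants (leader
dropped), 5′ (+9/+59) and 3′ (TTTTATTTT) extended guides, and multiplexed
arrays (one scaffold–spacer unit per spacer plus a trailing scaffold, bare
for linear arrays or wrapped in the ribozyme/ligation/linker shell for
circular ones).

Design choices worth knowing:

* **The 27-nt leader is not a cassette feature.** It is attached to
  leader-bearing variants and prepended at transcription; circular variants
  lose it with the 5′ ribozyme fragment. This keeps the published feature
  order of the simple variants (`Pre` = promoter, scaffold, spacer,
  scaffold) and makes the `d27` relationship exact: the `d27` transcript is
  the parent transcript minus the leader, nothing else.
* **Circularisation** cleaves at per-ribozyme offsets (default: the
  boundary facing the ligation sequence, i.e. the whole ribozyme leaves)
  and canonicalises the circle to start at the 5′ ligation junction;
  retained ribozyme residues from non-default offsets wrap to the 3′ end.
* **Linkers are stored core-first** (extension at the linker's 3′ end), so
  core positions align across candidates of different extension lengths.
* Spacer length bounds default to 20–23 nt and are configurable per Cas
  system.

## Folding

Two deterministic builtin engines are provided; the production-grade
predictor stays external (an `RNAfold` adapter is included, and a missing
binary raises a capability error rather than silently substituting the
builtin model).

**MFE engine.** Minimum free energy under a bundled nearest-neighbor model
that is deliberately coarse and editable, not Turner-parameterised:
stacking energies generated from per-pair strengths (GC 2.0, AU 1.0,
GU 0.5; stack = −0.8·(s₁+s₂) kcal/mol), logarithmic hairpin
(4.5 + 1.6·ln(s/3)) and interior/bulge (1.6 + 1.3·ln s, capped at 30
unpaired nt) penalties, and an affine multiloop term (3.4 close + 0.4 per
branch + 0.1 per unpaired nt). Exterior bases are free, so the open chain
scores exactly 0 and any reported structure has ΔG ≤ 0. Minimum hairpin
loop 3; wobble pairs allowed; pseudoknots excluded. The recursion is the
standard V/WM/WM2 decomposition; fills are numba-jitted, tracebacks are
Python with a fixed scan order so outputs are byte-identical across runs.

**Max-pair engine.** Nussinov-style maximum base pairing (ΔG reported as
−pairs in pseudo-units, flagged by `engine_id`). Tie-breaking is exactly
lexicographic: among maximal structures, pair the smallest i, then its
smallest feasible partner j, recursively. This makes outputs predictable
enough to design fixtures against (see below).

**Circular folding** uses the doubled-sequence reduction: tables are
filled on the concatenation with span < n and the optimum is taken over
all rotations (the optimum of any nested circular structure is reachable
from a cut in its exterior face). The face containing the chosen origin is
treated as a free exterior loop, so a structure whose origin face is a
hairpin-sized loop is slightly over-permitted relative to a strict
circular energy model; for the same reason the circular optimum is never
worse than the linear one. Structures whose pairs cross the input origin
are reported in a rotated frame (`origin` records the rotation); the pair
table is always in input coordinates.

**Oracle.** A memo-free recursive enumerator generates every nested,
min-loop-respecting structure of short sequences; a direct
loop-decomposition scorer evaluates any structure under the model. Both
engines are tested against exhaustive enumeration (all sequences to length
8, plus random longer ones) in linear and circular mode.

## Screening

The screen operationalises the published procedure with two thresholds the
original description leaves qualitative:

* **"Correct structure"** = per-motif pair recovery ≥ `min_pair_recovery`
  (default 1.0) and cross-pairs into the motif footprint ≤
  `max_cross_pairs` (default 0) — the strictest reading, configurable per
  screen. A motif anchored to a part occurring twice (the two scaffold
  copies) is checked at every occurrence.
* **"Structural similarity"** defaults to equality of coarse shape strings
  (helices collapsed to `[]`, loops dropped — length-robust across the
  5–7-nt extension range); a base-pair-distance mode (single linkage on
  the normalized symmetric difference over part-anchored coordinates) is
  available.

The pipeline folds the **linear precursor transcript** (leader included),
matching the read of the procedure in which correctness of the *ribozyme*
structure is checked — the ribozymes are gone from the ligated circle —
with circle folding available separately. Ranking uses the primary
engine's ΔG ascending with lexicographic linker tie-breaks; the top 10–20
(default 20) are grouped; the confirmation engine re-checks only those;
per group the most stable doubly-correct member is selected, and a group
with no such member selects nothing and is flagged. Candidate order is
canonicalised on ingest, so reports are independent of library order, and
every run emits a manifest (config hash, seed, engine ids).

Sampled libraries draw unique extension pairs by seeded rejection
sampling; exhaustive mode enumerates extension pairs behind a size guard
(the one-sided spaces are 4⁵ = 1,024 and 4⁵+4⁶+4⁷ = 21,504; the pair
space squares that). Extensions are uniform over the four bases with no
composition constraint.

Note an honest consequence of the strict defaults: under the max-pair
confirmation engine, its lexicographic tie-breaking tends to pair
stem-arm nucleotides with upstream filler C's whenever polyAC fillers
precede a stem, so full-recovery confirmation rarely passes on realistic
polyAC cassettes. Screens that should select candidates in production use
the external RNAfold adapter (or the MFE engine) for confirmation, or
relax `min_pair_recovery`; the default pairing of engines mirrors the
two-predictor design and is exercised as such by the tests.

## Fixtures

Real part sequences (Twister P3 U2A/P1, Tornado ligation stems, Cas12a/
CasRx direct repeats, Sp1 linkers) are user-supplied configuration. The
bundled fixtures are *synthetic stand-ins* with the documented lengths:
structured parts are designed hairpins with homopolymer G/C stem arms
around A loops, verified at creation to fold to their declared motif in
isolation under the builtin MFE engine; fillers are AC-rich like the
flexible linkers used in practice.

The **discrimination fixture** restricts the alphabet further (A-only
fillers, poly-A linker cores) so that the intact cassette has a unique
optimum under *both* engines — every C is a designed stem partner of
every G, and the max-pair tie-break then provably reconstructs each stem.
Its invading linker pair attacks the scaffold hairpin from both sides by
reverse-complement construction: a 5′ C₇ extension that the max-pair
tie-break prefers over the scaffold's own 3′ arm, and a 3′ extension
(revcomp of the scaffold loop-end + arm) that forms a longer, lower-energy
helix than the designed 5-bp stem under the MFE model. The preserving
pair therefore passes both engines with full recovery and the invader
fails both — a screen whose right answer is known by construction.

What the synthetic fixtures do **not** emulate: real Twister/scaffold
tertiary structure, G/U-containing natural fillers, spacer-dependent
misfolding, and Turner-accurate energetics. Passing tests demonstrate the
pipeline's logic (filtering, ranking, grouping, selection, determinism),
not wet-lab linker performance; real designs should be confirmed with
production predictors via the adapter, as the two-predictor workflow
intends.

Toy quantification tables mimic the assay shapes: a 14-site cleavage read
table with a few off-target sites per condition, a FACS count table, and
a 1/3/6/9/18-h transcription-shutoff series with 5% multiplicative noise
around half-lives of 2 h (linear) and 24 h (circular).

## Quantification

All statistics are the defining ratios computed exactly: SI sums reads
across sites before dividing (a per-site mode is exposed); cleavage
efficiency enforces the gating hierarchy (mNeonGreen⁻∩mCherry⁺ ≤ mCherry⁺
≤ total); fold change is a ratio of means with a 2^−ΔΔCt helper for Ct
inputs. Half-life uses ordinary least squares on ln(abundance) vs time
(closed-form, robust for 5-point series) rather than nonlinear fitting;
k ≤ 0 flags a stable species with t½ = ∞. Time-zero and reference-gene
normalisations only shift the intercept, so both are accepted. No
hypothesis testing is performed — replicate-level ANOVA/t-tests on wet-lab
data are out of scope.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the folding oracle
exhaustively to length 8 (87,380 sequences) plus 500 random sequences to
length 16; screen-property sweeps use 100 random 50-candidate libraries
on a compact (~160-nt transcript) cassette with the max-pair engine, with
structures folded once and re-filtered across threshold settings; the
quantification checks use 1,000 random tables and a 100-replicate
Monte-Carlo half-life recovery at 5% noise. Every stochastic step is
driven by an explicit seed, and identical configurations produce
byte-identical reports, registries and data files (the only timestamps
live in run manifests).

## Known limitations

* The bundled energy model ranks plausibly but is not quantitative;
  absolute ΔG values are not comparable to laboratory predictors.
* Max-pair confirmation is intentionally blunt (see above).
* Circular folding's origin-face simplification can admit a sub-min-loop
  origin loop.
* No PAM/genome-level spacer design, cloning simulation, promoter
  modelling, or prediction of editing efficiency from structure.
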