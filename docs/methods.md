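# Methods

`pamprospector` reconstructs, as a tested pipeline, the chain of analyses by
which a Cas9 nuclease's protospacer-adjacent-motif (PAM) specificity is
discovered and characterized: find orthologs whose PAM-contacting residues
have diverged, read the natural PAM off phage genomes targeted by the host's
CRISPR spacers, confirm position-wise preferences in a reporter-sort screen,
quantify cleavage on all motif variants in vitro, and measure how much of a
genome the motif makes targetable.

## Ortholog mining

Candidate orthologs are compared to a reference nuclease (SpyCas9-like, with
PAM-contacting arginines such as R1333/R1335) by optimal global alignment
under a substitution matrix with affine gap costs. Conventions:

- **Gap model.** A gap of length L costs `gap_open + L * gap_extend`
  (EMBOSS needle convention); terminal gaps are penalized. Defaults:
  BLOSUM62, open 11, extend 1 — the standard protein settings.
- **Percent score.** `100 * score(ref, query) / score(ref, ref)`, clamped
  below at 0. The self-score is the sum of diagonal matrix entries (identity
  is always the optimal self-alignment for matrices with maximal diagonals,
  as in the BLOSUM family), so a self-alignment scores exactly 100. The
  ortholog filter keeps queries at or above the threshold (default 70%),
  boundary inclusive.
- **Determinism.** The alignment engine (Biopython's `PairwiseAligner`)
  returns a deterministic first traceback; the raw score, which is the only
  alignment quantity consumed downstream, is independent of traceback order.
  Optimality is verified in the test suite against an exhaustive-recursion
  oracle on short sequences.
- **Coordinates.** Residue positions are 1-based everywhere, matching how
  contact residues are named in the field.

Conservation around the contacts is summarized over a single odd-length
window (default 11 positions) spanning all contact positions. Gaps and X
residues are excluded from column counts; the information content of a
column is `log2(20) − H` bits, where `H` is the Shannon entropy of its
residue distribution, so a fully conserved column reaches ~4.32 bits and a
uniform column 0. Columns covered by fewer than half the orthologs are
flagged in the log rather than dropped.

Hybrid bookkeeping (`design_hybrid`) records PAM-interacting-domain grafts:
the product keeps the scaffold through a junction position and continues
with the donor from the residue its alignment places opposite junction+1.
The junction is mapped through a fresh scaffold-donor alignment because
published figures typically mark the graft point graphically rather than by
residue number; the junction is therefore user-configurable. Point mutations
(e.g. an efficiency pair like R221K/N394K, then a fidelity mutation like
R691A) are applied only after verifying the expected pre-mutation residue,
so a mislabeled design fails loudly.

## PAM inference from spacer-to-phage mapping

Spacers are matched to phage genomes by exact sliding-window Hamming
comparison on both strands — no indels, default budget 2 mismatches. At desk
scale (≤ Mb genomes) this brute-force scan is exact and fast, so no seeding
or indexing heuristics are involved; equivalence with a per-offset oracle is
part of the test suite. Coordinates are 0-based half-open on the forward
strand; minus-strand hits report forward coordinates (BED convention).

The candidate PAM is the flank immediately 3′ of the protospacer on the
spacer-matching strand (type II-A geometry: the same convention that puts
5′-NGG-3′ next to SpyCas9 targets), default 8 nt to cover an 8-mer
randomized-PAM library. Flanks truncated by a genome edge are excluded and
logged. Flanks accumulate into a position frequency matrix; per-position
information content is Schneider-style `IC_j = 2 − H_j` bits against a
uniform DNA background, with no small-sample correction (the observation
count is reported alongside, and a correction would obscure hand-checkable
toy examples).

Consensus calling: at each position the IUPAC code covering every base whose
frequency is at least 0.25 of the top base's frequency; positions with
IC < 0.2 bits are forced to N. The 0.25-relative rule deliberately admits
secondary bases, so at moderate enrichment a planted base may come back
inside a two-letter code rather than alone; "recovery" therefore means the
planted base is covered by a constrained call. Calls from fewer than 10
flanks (configurable) are emitted with a low-confidence flag instead of
failing — natural CRISPR arrays are often that small.

Optionally, each spacer's flanks can be down-weighted by its number of hits
(`weight_multi_hits`), preventing repetitive phage regions from dominating
the matrix; counts then become fractional.

## Reporter-sort enrichment

Traces enter as per-position base-fraction tables (TSV), not chromatogram
files: the analytic content is the relative peak heights, and binary trace
parsing belongs upstream. Raw heights are row-normalized; enrichment is
`log2((post + ε)/(pre + ε))` with ε = 0.01 on proportions, applied to both
sides so identical profiles give exactly zero and absent bases stay finite.
A base is called at a position when its enrichment reaches 1.0 log2 unit
(2-fold, configurable); the set of called bases is IUPAC-coded, N when
empty. The screen itself reports preferences qualitatively, so the numeric
threshold is this package's convention, chosen at the value where a
uniformly-represented library member must roughly double its share.

## Cleavage quantification and kinetics

The cleaved fraction of a gel lane is
`Σ product-band intensity / (Σ product-band intensity + substrate intensity)`,
computed from band-intensity tables; gel images and pixel integration are
out of scope. Multiple product bands are summed without weighting. The
statistic is scale-invariant, so unnormalized densitometry units are fine.

Lanes labeled with 4-letter PAMs of the form xAAy assemble into a 4×4
matrix keyed by the 5′/3′ bases around the adenine dinucleotide; replicates
aggregate as mean and sample standard deviation (n−1 denominator), with the
completeness check exhaustive over all 16 cells.

Time courses are fit to the standard irreversible single-exponential model
`f(t) = A·(1 − e^(−kt))` by bounded least squares (A ∈ [0, 1.05] to absorb
densitometry overshoot, k ≥ 0; tolerances 1e−14 so noiseless data recover
parameters to ≲1e−9). Initialization is deterministic: A₀ = max observed
fraction, k₀ = 1/(time of first half-maximal point). A flat time course
returns k = 0 with `converged=False`, because the rate is unidentified
there. The exponential form is this package's summary model for comparing
digest rates; it is not asserted as the mechanism behind any published
time-course figure.

## PAM landscape

`pam_density(seq, motif)` is the fraction of motif-length windows matching
the motif; with both strands on, a window counts if it matches forward or
its reverse complement matches (strand union, indexed by forward start). The
denominator is the window count `L − |motif| + 1` summed per record (no
bridging across records), not genome length; windows containing N are
excluded from both sides, since real assemblies contain gaps. These
conventions are explicit because published percent-of-genome figures rarely
spell theirs out; all of them are configurable enough to test alternatives
(forward-only mode, any IUPAC motif). Dinucleotide frequencies use
overlapping windows at step 1 with the same N-exclusion, and forward-only AA
density equals the AA dinucleotide frequency by construction — a cross-check
in the test suite.

Site enumeration reports, per match, the motif occurrence and a candidate
protospacer of fixed length (default 20 nt) 5′ of the PAM on the PAM's
strand; matches whose protospacer would leave the sequence are counted
separately rather than silently dropped.

## Synthetic data

Generators exist so every stage runs and is validated with no downloads.
Each takes an explicit seed, draws from its own `numpy.random.default_rng`
stream, and returns a `TruthRecord` (generator name, seed, planted
parameters) sufficient to predict the expected downstream result.
Regeneration with the same seed is byte-identical.

Default study conditions:

| generator | defaults | rationale |
|---|---|---|
| `gen_ortholog_family` | i.i.d. substitution per site; rate ≤ 0.5 | 0.12 ≈ 85% percent score, 0.35 ≈ 55% for a 360-residue reference — tiers straddling the 70% filter by ≥15 points |
| `gen_phage_cohort` | 5 genomes × 20 kb, 40 protospacers of 20 nt, flank 8, planted profile N/A:0.9/A:0.9/N, spacer error 2% | a realistic handful of phages and spacers for a genus-level CRISPR survey; 90% per-position enrichment matches a strong natural motif |
| `gen_trace_pair` | region 8 nt, fold 4, peak CV 5% | 8-mer randomized library; 4-fold is the weakest selection the 2-fold call threshold should still resolve |
| `gen_gel_data` | total intensity 10⁴, multiplicative CV | densitometry noise scales with band intensity |
| `gen_timecourse` | k = 0.3/min, plateau 0.9, t = 1..8 min, σ = 0.02 | a digest mostly complete within minutes, sampled through its rise |

Noise on trace fractions and gel bands is multiplicative
(coefficient-of-variation), the standard behavior of peak-height
measurements; trace rows are renormalized after perturbation so profiles
stay valid.

What the generators do **not** emulate — and therefore what passing tests do
not show about real data: phylogenetic correlation between orthologs, indel
structure, or domain architecture; phage genome composition, repeats, or
shared ancestry between genomes (uniform background, GC knob only);
sequencing chemistry artifacts in traces; lane-to-lane gel effects or band
smearing; enzyme-specific deviations from single-exponential kinetics.
Conclusions about real inputs rest on the conventions above, not on the
generator's realism.

## Problem sizes and determinism

The validation suite runs the full inference on 5 × 20 kb cohorts, oracle
comparisons on 50 random genomes ≤ 2 kb and 200 protein pairs ≤ 8 residues,
and 50–200-seed replicate studies for the stochastic recovery rates — sizes
at which the brute-force oracles remain exact and the whole suite completes
in seconds. All randomness flows through explicit seeds; property-based
tests run derandomized.

## Known limitations

- The Hamming search tolerates substitutions only; a protospacer carrying an
  indel relative to its spacer is invisible.
- Percent-score filtering depends on the gap convention above; tools using
  `open + (L−1)·extend` or unpenalized terminal gaps will score boundary
  cases differently.
- The consensus caller models positions independently (PFM); correlated
  positions (e.g. dinucleotide constraints) are only visible through the
  letters they share.
- Kinetics fits assume a single exponential phase; biphasic digests will
  return an effective rate with inflated residuals rather than a warning.
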