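# Methods

This note documents the models and numerical choices behind gpcrminer:
what each stage computes, the parameters that matter, what the synthetic
benchmark does and does not establish, and the design decisions taken
where the design was genuinely open.

## Profile HMM engine

Family and domain models are Plan-7-style profile HMMs built from seed
alignments.

* **Match-column rule.** A column whose gap fraction is ≤ 0.5 becomes a
  match state; the boundary case *is* a match state (pinned for
  reproducibility). Emissions use additive Laplace pseudocounts
  (weight 1 per residue over the 20 canonical amino acids); `X` is
  treated as a missing observation during estimation and scores 0
  (background odds) during alignment. Transitions are counted from each
  row's path through the match columns with +1-per-allowed-transition
  smoothing. The local model has no D↔I transitions; insertions adjacent
  to deletions are folded into the direct delete move.
* **Local alignment mode.** Uniform entry log₂(1/m) into any match
  state and free exit from any match state. Scores are log₂-odds
  against a background model (flat 1/20 by default, overridable), so
  residues flanking the local alignment cancel. Viterbi and forward run
  in numba-compiled dynamic programming; the test suite proves both
  equal brute-force path enumeration on toy models and that
  forward ≥ Viterbi everywhere.
* **E-values.** Each profile is calibrated by scoring `n_random = 1000`
  random background sequences of length 350 and fitting a Gumbel
  distribution by maximum likelihood (`scipy.stats.gumbel_r.fit`);
  `E(s) = N·(1 − exp(−exp(−λ(s−μ))))` with `N` the number of sequences
  scanned (per-proteome database size). Calibration attaches (λ, μ)
  without touching emissions or transitions. For strong hits the E-value
  underflows double precision, so log₁₀E is computed analytically on the
  Gumbel tail (`log₁₀E ≈ log₁₀N − λ(s−μ)/ln10`); all ranking and the
  scatter discriminant use log-space E-values. Gumbel fitted on Viterbi
  scores; forward is reported but not used for E-values — simpler
  calibration, adequate for family-level discrimination.
* **Best domain per region.** Hits at E ≤ 10 (configurable) are kept
  greedily in E-order; a hit is dropped if it overlaps an already-kept
  hit over more than half of the shorter envelope. One best alignment
  is taken per profile per sequence; tandem repeats of the *same*
  domain are therefore not enumerated (a known limitation — the domain
  vocabulary used here has no benchmark case needing it).
* **Consensus.** Plurality rule: the maximum-probability residue per
  match state, ties broken alphabetically. Proven equal to an
  independent per-column argmax oracle.

## Transmembrane topology

A deliberately simple, fully self-contained hydropathy predictor stands
in for external topology tools: windowed Kyte–Doolittle averages
(window 19, ends shrink), maximal runs ≥ 1.5 are segments, runs
separated by ≤ 3 residues merge, runs < 15 residues are discarded. Loop
labels assume an extracellular N-terminus (ICL1 after TM1, ECL1 after
TM2, …), the universal GPCR orientation. The acceptance filter keeps
6 ≤ nTM ≤ 9 inclusive, with a whitelist for manual inclusions (the
biological precedent being a lone 5-TM cAMP-receptor representative
worth keeping). Externally predicted topologies can be imported from
TSV and then drive every downstream stage bit-for-bit. The filter is
applied to full-length sequences, and uniformly to GRAFS and
fungal-specific candidates.

## Redundancy

Greedy incremental clustering within each proteome: sequences sorted by
length (descending; ties by id), each joins the first cluster whose
representative it matches at ≥ 0.90 identity under the shorter-sequence
convention (identical aligned positions / length of the shorter
sequence). Reported identity *statistics* instead use the
alignment-column convention (identical pairs / all alignment columns,
gap columns included) — two conventions on purpose, each matching the
tool it emulates, both on one global aligner (BLOSUM62, gap open −11,
extend −1). The short-word prescreen of fast clustering tools is
omitted: full pairwise identity against representatives only, trading
speed for exactness at desk scale.

## Classification and reclassification

Family = family of the minimum-E hit among the family models (Git3 and
Git3_c collapse to one family); nutrient-sensor hits are honoured only
at E ≤ 1e−25. The Rhodopsin/cAMP boundary gets special treatment
because the two profile models score near-duplicate E-values on
borderline sequences:

* the scatter coordinate of a sequence is (log₁₀E vs 7tm_1, log₁₀E vs
  Dicty_CAR); a gap below 1.0 log-unit flags the call ambiguous;
* diagnostic motifs are searched only inside their anchored topological
  region ± 5 residues (absorbing small TM-boundary error). Default
  patterns: `[DE]RY` (TM3) and `NP..` (TM7) for Rhodopsin; `N.Y`,
  `NS.Y` (TM3) and `N[SA]..Y` (TM7) for cAMP — the parenthetical
  notation N(S)xY is encoded as both readings, neither privileged —
  plus shared ICL1 `[RK]`, TM2 `D`, and ECL1/ECL2 `C`, and the
  Adhesion-conserved set (W in TM3, P in TM4/5, G in TM7);
* a 7tm_1-best call with no D/ERY-class motif but a cAMP TM3 motif
  becomes cAMP (and symmetrically back). Motif precedence applies
  regardless of the E-value margin; the ambiguity band only flags calls
  for tree-based review. Reclassification is idempotent.

Conservation profiles report the modal residue per column over non-gap
characters; the "conserved" threshold is ≥ 0.90 (inclusive reading of a
boundary that sources state both ways), configurable.

## Domain architecture

Only residues before TM1 are scanned; kept hits need E ≤ 0.01. Two
cutoffs circulate for this verification step in the literature this
procedure follows (0.01 in the procedural description, 0.1 in figure
captions); the default here is the procedural 0.01, configurable. The
domain vocabulary is data: a manifest maps domain names to seed
alignments, so the set (GPS, ANF_receptor, EGF_CA, Calx-beta, …) can
grow without code changes.

## Phylogeny

Alignments are the match-state projection of each sequence's Viterbi
path onto the anchoring family profile — deterministic, reuses the one
scoring engine, and restricted to the modelled 7TM region by
construction (insert residues dropped, unmatched states gapped).
Distances are p-distances over columns ungapped in both rows (Poisson
correction available); trees are canonical Saitou–Nei neighbor joining
with negative branch lengths clamped to zero and the deficit moved to
the sister branch; support comes from 500 column-resampling bootstrap
replicates (taxa canonically ordered so support is input-order
invariant). Family claims are monophyly statements: does one edge
separate exactly the family's leaves? Bayesian and maximum-likelihood
tree inference are deliberately out of scope; the cluster-separation
claims this package makes are testable with NJ + bootstrap, and
alignments export to FASTA/PHYLIP for external tools.

## Synthetic benchmark

The generator is the package's study-condition definition, co-designed
with the predictor defaults (the constants live beside each other):

* TM stretches are 25 residues drawn from a strongly hydrophobic pool
  (I/L/V/F/A-weighted, mean KD ≈ 3.7); loops are 15 ± 2 residues from a
  mildly hydrophilic pool (mean ≈ −1.5) — hydrophilic enough to break
  runs, mild enough that segment ends survive the ≥ 15-length rule even
  with hydrophilic motifs planted near TM ends (motifs are kept ≥ 5
  residues inside their region for the same reason).
* Each family derives from a seeded consensus core; members mutate from
  it at rate 0.20 (region-aware pools). The cAMP core is the
  Rhodopsin-like core diverged at 0.30 — the two families are close by
  construction, which is what makes the dual-model scatter and the
  joint tree informative. Chimeras sample the Rhodopsin core with the
  cAMP motif set and no D/ERY, so they are Rhodopsin-best by E-value
  and reclassify on motifs; in the joint tree they attach to the
  Rhodopsin cluster (their core provenance), which is why the pipeline
  reports joint-tree monophyly as diagnostic output while the
  monophyly *benchmark* uses chimera-free two-family replicates.
* Default benchmark (seed 1234): 40 Rhodopsin, 40 Adhesion, 40
  Glutamate, 40 Frizzled and 32 cAMP receptors (8 of the cAMP being
  chimeras; each non-chimera family includes near-duplicates at
  point-mutation rate 0.05), 40 hydrophilic decoys, 10 five-TM
  fragments — 250 sequences. Adhesion N-termini are 2–66 residues with
  no domains; Glutamate N-termini are 160–400 residues carrying an
  ANF_receptor-like cassette. Real fungal Glutamate N-termini reach
  ~1700 residues; the generator's range is scaled to desk size since
  the annotator has no length dependence. Domain families are synthetic
  (name-seeded consensi from the hydrophilic background so they never
  masquerade as TMs).
* Truth labels live only in the returned table, never in pipeline
  inputs.

**What passing these tests shows — and does not.** The benchmark proves
the machinery: segment recovery, E-value discrimination between related
profile models, motif-anchored reclassification, redundancy collapse,
architecture recovery and cluster separation all work end-to-end under
controlled signal. It does not emulate real proteome hazards: profile
models trained on distant homologs, compositional bias shared between
families, signal peptides mistaken for TM1, alternative topologies, or
databases whose version changes the hit set. Real-data runs should
treat the TM thresholds and the report cutoff as tunables and use the
topology-import path when a dedicated predictor is available.

## Numerical and degenerate-input choices

* Seeds: every stochastic step takes an explicit seed; sub-seeds derive
  from a master seed via SHA-256 of tagged strings (kept < 2³¹).
* Ties: consensus and conservation break alphabetically; equal-length
  cluster candidates break on id; scan ties break on (log₁₀E, −bits,
  model name).
* Degenerate inputs: empty FASTA, duplicate ids, zero match columns,
  zero-variance calibration scores, uncalibrated profiles, non-symmetric
  distance matrices, improper monophyly queries and pairs sharing no
  ungapped columns are all hard errors with named offenders; a pair
  sharing no columns inside a bootstrap *replicate* falls back to
  distance 1.0 rather than aborting the replicate.
* The whole pipeline is byte-deterministic given (inputs, config, seed);
  the CLI's stage artifacts round-trip byte-identically.

## Problem sizes

Defaults used by the shipped analyses: 250-sequence benchmark proteome,
profiles of ~265 match states, 1000-sequence Gumbel calibration,
100-replicate bootstrap inside the pipeline report and 500-replicate
bootstrap (20 seeded replicates, 10+10 taxa) for the monophyly check.
These sizes were chosen as the smallest at which every effect being
tested is comfortably resolved.
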