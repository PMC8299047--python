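# Methods

This note documents the models and procedures implemented in `melamap`, the
assumptions behind them, the parameters that matter, and what the synthetic
data does and does not emulate.

## Normalization model

Protein intensities are assumed multiplicative: a protein's measured linear
intensity in sample *j* of batch *b* is modelled as
`2^(a_i + β_b + s_j + ε_ij)` with true log2 abundance `a_i`, batch offset
`β_b`, sample offset `s_j` and noise `ε`. Two corrections are applied in
sequence:

1. **Intra-sample centering** — log2 transform, then subtract each sample's
   median of detected values. This removes `s_j` plus whatever share of
   `β_b` is visible in the sample median. It is idempotent and leaves
   missing entries missing.
2. **Inter-batch correction** — reference proteins are those detected in
   100% of samples of the whole cohort whose coefficient of variation
   (CV = 100·σ/μ, sample standard deviation with n−1, computed on the
   **linear** scale per batch) stays strictly below 60% in every batch. The
   median log2 abundance of the reference set within each batch is
   subtracted from all values of that batch, so residual batch offsets that
   survive centering (e.g. induced by batch-dependent missingness) are
   removed relative to a stable panel.

Design choices where the procedure was open: the CV scale (linear) and
denominator (n−1) are conventions of this package; "identified in all
samples" means zero missing values across the whole cohort, not per batch;
missing values are never imputed and all medians use detected values only;
ranking ties in the relative-abundance map break by protein id so ranks are
a reproducible permutation. The reference set is data-driven (threshold
rule), not a fixed protein list; the count 45 is a property of the synthetic
construction, which plants exactly 45 qualifiers.

A consequence worth knowing: in noise-free data the sample median already
absorbs the batch offset completely, so the correction stage measures only
*residual* batch structure. The batch offsets themselves are exactly
recoverable from the uncentered log2 matrix (tested).

## Quantification

TOP3 reports the mean of the three largest peptide areas over unique and
razor peptides; with fewer than three eligible peptides the mean of the
available ones is used, and a protein with none is omitted rather than
erroring. Ties at the top-3 boundary are harmless (the mean does not depend
on which tied record is chosen). TMT roll-up sums reporter intensities per
channel over unique peptides only; razor peptides are excluded and
zero-intensity channels contribute zero. No isotope-impurity correction and
no protein inference are performed — protein assignments are taken as given.

## Proteogenomic digestion

Trypsin cleaves after K/R, Arg-C-like digestion after R only; in both modes
cleavage is suppressed when the next residue is proline. Coordinates are
1-based inclusive, matching mutation nomenclature (Q61K). At `max_missed`
= k, every reported peptide is the concatenation of up to k+1 adjacent
fully-cleaved segments; the 0-missed peptides tile the protein exactly.

A mutant-specific call digests the substituted proteoform and flags each
peptide overlapping the mutated position (plus, when the substitution
creates a new cleavage site, the peptide starting immediately after that
site — this is how a Gln→Lys substitution yields a shortened peptide lacking
the wild-type C-terminal tail) as *distinguishable* iff its sequence is
absent from the wild-type digest at the same missed-cleavage limit. A
substitution can in principle both create and destroy sites; the reported
`cleavage_change` prioritizes `gained`. Unexpected peptide N-termini
(preceding residue not K/R) generate *indirect* candidate mutations of that
residue to K and to R; candidates are evidence only and never auto-promoted.

Peptide uniqueness uses exact substring matching with I and L treated as
equal by default (they are isobaric and indistinguishable by standard MS);
a peptide is unique when its hits map to a single gene symbol.
Missing-protein acceptance follows the two-peptide rule: at least two
uniquely mapping peptides of ≥9 residues. Post-translational labels
(TMT, carbamidomethylation) do not alter residue strings and are ignored
for sequence identity. Fully tryptic peptides are assumed (no semi-tryptic
search).

## Transcriptome integration

Transcripts are kept when their maximum read count over samples reaches the
threshold (default 10) — the "at least ten reads" criterion is ambiguous
between per-sample and aggregate readings; maximum-over-samples is the
implemented and configurable choice. Transcripts collapse to genes by
per-sample maximum. Gene medians are computed on log2 of positive counts
(library-size normalization is out of scope; counts are taken as given).
Protein and transcript medians are each affinely scaled to [10, 35] before
differencing (difference = protein − transcript); Pearson correlation is
unaffected by this scaling.

The 1D enrichment score for a term with `n_in` members among `n` ranked
genes is `s = 2(R̄_in − (n+1)/2)/(n − n_in)` with ascending mid-ranks: +1
when members occupy all top ranks, −1 at the bottom, 0 in expectation under
exchangeability, invariant under monotone transforms of the scores and
antisymmetric under negation. Significance is a two-sided Mann–Whitney U
test, adjusted by Benjamini–Hochberg across terms. Terms with fewer than 5
members present, or covering every scored gene, are skipped.

## PTM analysis

Phosphosites with localization probability ≥ 0.75 (inclusive) are Class I;
the threshold is one configurable parameter. Site windows are 15 residues
centered on the acceptor, padded with `_` at protein termini. Motif search
is motif-x-style: per central residue (S, T, Y separately), repeatedly fix
the (position, residue) pair minimizing the binomial tail probability of its
foreground count given the background frequency, filter both sets, and stop
when no pair reaches `p_cutoff` (default 1e-6) with `min_occurrences`
(default 20) foreground instances; a finished motif's instances are removed
and the search restarts. Ties break by position index then residue, so the
search is deterministic. Kinase prediction matches enriched motifs against a
small curated kinase→motif table shipped with the package — a synthetic
stand-in fixture covering textbook consensus motifs, not a reconstruction of
any production kinase-substrate database; counts of enriched motifs and
predicted kinases on real data depend entirely on that table. Kinome
coverage is |identified ∪ predicted| / |kinome|.

Acetylation occupancy is `100·L/(L+H)`: the light channel is endogenous
acetylation, the heavy channel carries the chemically acetylated
(heavy-isotope) remainder of the site, so their ratio is the site
stoichiometry. Both channels zero → undefined (flagged, excluded from
summaries but counted). Per-sample summaries use medians and quartiles;
"average occupancy below 15%" is evaluated as the median of per-sample
medians (the median is robust to the long right tail of a low-occupancy
Beta distribution).

## Plasma profile

NSAF normalizes spectral counts by protein length and by the cohort total,
so abundances sum to one and are invariant to uniform count scaling. Protein
length comes from the FASTA when available (mismatching table lengths are
warned and overridden). Blood-origin = identified in plasma with no tissue
transcript evidence for the gene; the per-sample blood fraction is
100·|sample ∩ blood|/|sample|. Immunoglobulin flagging is a documented
gene-prefix heuristic (IGH/IGK/IGL). The FDA plasma-marker panel is a small
editable GMT fixture of well-known cleared markers.

## Synthetic data

The generators define the study conditions used throughout the tests:

- **Abundance matrix** (default 2000 proteins, 5 batches × 20 samples):
  true log2 abundances uniform over six orders of magnitude (base 10 in
  log2 units); batch offsets N(0, 1 log2), sample shifts N(0, 0.3 log2);
  per-protein noise 0.2 log2 for the 45 planted references and
  uniform(0.3, 1.2) otherwise; detection is Bernoulli with a logistic curve
  in true log2 abundance (midpoint 13, slope 1.5), making detection
  probability monotone in abundance. References are forced detected
  everywhere and kept safely under the CV criterion; any non-reference
  protein that happens to satisfy both criteria has one value removed, so
  the planted set is exactly the qualifying set. A switch disables this
  enforcement for degenerate noise-free scenarios in which all proteins
  legitimately qualify.
- **Paired transcriptome**: gene-level log2 transcript abundance
  `t = ρ·z + √(1−ρ²)·e` around standardized protein medians, so the
  protein–transcript Pearson correlation converges to ρ (default 0.44);
  counts are 2^t with small per-sample noise, rounded to integers (counts
  are large enough that quantization is negligible). Configurable fractions
  of transcript-only and protein-only genes.
- **Acetylome** (default 60 samples: 16 primary, 23 lymph-node, 21 other
  metastases; 200–2000 sites per sample): per-site occupancy θ ~ Beta(1, 9)
  (mean 10%, median ≈ 7.4%), light = θ·I·ε and heavy = (1−θ)·I·ε′ with
  log-normal site intensity I and independent multiplicative noise of ln-sd
  0.15 — at which the median absolute occupancy recovery error stays below
  2 percentage points.
- **Phosphopeptides**: windows with uniform 5% flank composition and one
  planted motif at a configurable foreground fraction (default R-x-x-S# at
  30%).
- **Plasma**: 1000 plasma proteins, 112 planted blood-origin genes withheld
  from the tissue transcriptome, 84% of them immunoglobulin-styled; blood
  genes enter each tissue sample with probability 0.45, keeping per-sample
  blood fractions well below 3%.
- **Toy proteome**: six proteins embedding the authentic wild-type local
  sequence contexts of the driver-mutation panel (BRAF V600E, NRAS
  Q61K/Q61R/G12A, KRAS G13D, KIT N566D, CDKN2A P114L, GNA11 N266K) at their
  true residue coordinates, with random K/R/P-free filler elsewhere so the
  contexts' cleavage structure is undisturbed.

All generators derive child seeds deterministically from one master seed
(fixed per-stream spawn keys), so identical seeds give bit-identical
outputs.

What the synthetic data does **not** emulate: peptide-level interference and
shared peptides, intensity-dependent (rather than abundance-dependent)
missingness, correlated noise across proteins, isotope impurities, real
codon/transcript structure, or the composition of real plasma. Passing
recovery tests on this data therefore demonstrates correctness of the
implementations under the stated generative assumptions, not robustness to
every artefact of real LC-MS/MS cohorts.

## Problem sizes and numerics

Test and acceptance runs use the generator defaults above (2000 × 100
abundance matrix; 10 000 genes for correlation recovery; 10 000 label
permutations for enrichment-null calibration; 100 null simulations for
motif type-I control), chosen as the smallest sizes at which the targeted
statistical tolerances (±0.03 on ρ at n = 10 000; ≤5 false motifs in 100
null runs) are meaningful. Medians of even-length vectors follow the
mid-mean convention of numpy. Degenerate inputs error loudly rather than
returning silent defaults: empty reference sets warn and pass through,
undefined occupancies and empty samples are flagged as NaN, constant
vectors cannot be min-max scaled.
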