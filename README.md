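# melamap

Analysis toolkit for deep melanoma tumor proteomics. It implements, as a
tested and reusable library, the computational stages needed to turn
peptide-level mass-spectrometry quantification of a large multi-batch tumor
cohort into a ranked protein abundance map and its downstream readouts:
mutation-bearing (proteogenomic) peptide detection, proteome–transcriptome
integration, phospho/acetyl PTM quantification including acetylation-site
stoichiometry, kinome coverage, and plasma profiling by spectral counting.
A seeded synthetic-data module generates inputs with the statistical
structure the analysis assumes, so every stage is testable without access to
raw cohort data.

## What it computes

- **Quantification** — label-free TOP3 roll-up (protein abundance = mean of
  its three most intense unique-or-razor peptide areas) and TMT roll-up
  (per-channel sum of reporter intensities over unique peptides).
- **Normalization** — log2 transform with per-sample median centering, then
  inter-batch correction: proteins detected in 100% of samples with
  per-batch CV = 100·σ/μ < 60% act as reference proteins, and each batch is
  shifted by the median abundance of that set. The result is a per-protein
  median relative abundance with detection counts and ranks.
- **Mutation proteogenomics** — in-silico tryptic digestion (cleavage after
  K/R, suppressed before P; configurable missed cleavages; Arg-C-like mode
  cleaving after R only), single-residue substitution of driver mutations
  (e.g. NRAS Q61K), and derivation of the mutant-specific peptides that are
  absent from the wild-type digest — including the shortened peptides
  produced when a mutation to K/R introduces a new cleavage site. Peptide
  uniqueness uses substring search with I/L equivalence; missing-protein
  claims follow the two-peptides-of-≥9-residues rule.
- **Transcriptome integration** — transcript filtering (≥10 reads),
  gene-level overlap and human-proteome coverage, Pearson correlation of
  gene-matched protein and transcript medians (optionally restricted to
  transcripts detected in ≥99% of samples), and 1D annotation enrichment of
  protein-minus-transcript differences: for a term with n_in members among n
  ranked genes, s = 2(R̄_in − (n+1)/2)/(n − n_in) ∈ [−1, 1] with a two-sided
  Mann–Whitney test and Benjamini–Hochberg adjustment.
- **PTM analysis** — Class I phosphosites (localization probability ≥ 0.75),
  15-residue site windows, iterative motif-x-style binomial motif
  enrichment, kinase prediction from enriched motifs, and kinome coverage
  (identified ∪ predicted kinases). Acetylation-site occupancy is
  100·L/(L+H) from endogenous (light) and heavy-isotope chemically
  acetylated signal.
- **Plasma profile** — NSAF abundances, NSAF_i = (SpC_i/L_i)/Σ_j(SpC_j/L_j);
  blood-origin classification (plasma proteins without tissue transcript
  evidence) and per-sample blood fractions.

## Worked example

```python
import numpy as np
from melamap.synthetic import SimConfig, gen_abundance_matrix, gen_acetylome, gen_toy_proteome
from melamap.normalize import normalize_pipeline
from melamap.proteogenomics import mutant_specific_peptides
from melamap.ptm import occupancy_table, occupancy_distribution

cfg = SimConfig(seed=1)
matrix, truth = gen_abundance_matrix(cfg)
res = normalize_pipeline(matrix)
span = (res.abundance_map["median_abundance"].max()
        - res.abundance_map["median_abundance"].min()) * np.log10(2)
print(f"reference proteins selected: {len(res.refset)} "
      f"(planted: {len(truth.reference_ids)})")
print(f"abundance map spans {span:.1f} orders of magnitude "
      f"over {len(res.abundance_map)} proteins")

proteome, panel = gen_toy_proteome(seed=0)
nras = next(p for p in proteome if p.gene == "NRAS")
q61k = next(m for m in panel if m.label == "Q61K")
call = next(c for c in mutant_specific_peptides(nras, q61k)
            if c.missed_cleavages == 0 and c.start <= 61 <= c.end)
print(f"NRAS Q61K mutant-specific peptide: {call.peptide} "
      f"(cleavage {call.cleavage_change})")

acetyl, _ = gen_acetylome(cfg)
per_sample, _ = occupancy_distribution(occupancy_table(acetyl))
print(f"grand median acetylation occupancy: "
      f"{per_sample['median'].median():.1f}% over {len(per_sample)} samples")
```

prints

```
reference proteins selected: 45 (planted: 45)
abundance map spans 6.1 orders of magnitude over 2000 proteins
NRAS Q61K mutant-specific peptide: QVVIDGETCLLDILDTAGK (cleavage gained)
grand median acetylation occupancy: 7.6% over 60 samples
```

The reference filter recovers exactly the 45 planted low-variability
proteins from a 2000-protein, 5-batch matrix; the normalized map spans the
expected six orders of magnitude; the Q61K substitution introduces a tryptic
cleavage that yields a shortened mutation-specific peptide; and the
simulated acetylome shows the low site occupancy typical of tissue
acetylation stoichiometry.

A `melamap` console script exposes the same stages from the shell
(`melamap simulate|quantify|normalize|mutpep|integrate|ptm|plasma --help`).

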