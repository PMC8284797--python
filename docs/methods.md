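# Methods

## Input model and nomenclature

HLA genotypes arrive one row per individual with two columns per gene
(`A_1`/`A_2`, ...), alleles written in colon-separated nomenclature
(`GENE*F1:F2:F3:F4`, fields of 2-3 digits, up to four fields, optional
expression suffix N/L/S/C/A/Q). Parsing is strict — legacy separator-less
names (`A*0201`) are rejected — but validation of whole tables is
advisory: `validate_calls` reports malformed or unknown cells without
mutating or discarding data, so partially typed cohorts stay usable.
Resolution reduction truncates fields and is idempotent; the expression
suffix is dropped on actual truncation because it annotates the
full-resolution sequence, and reducing to an allele's own resolution is
the identity. N-suffixed (null) alleles are kept by default; protein-level
transforms accept a `drop_null` flag to treat them as missing.

Grouping dictionaries (supertypes, G groups, NK ligands, user tables) are
two-column TSVs with a declared field resolution in the header; a query
allele is reduced to that resolution before lookup and maps to at most one
group (checked at load). Bundled dictionaries cover common alleles and are
deliberately editable: group assignments in this field change with
database releases, so the file, not the code, is the source of truth.

## Alignments and amino-acid expansion

Protein alignments use the conventional condensed layout: an explicit
reference row followed by rows coded `-` (identity), `*` (unknown), `.`
(indel), position labels from the header (1-based mature-protein
numbering, negatives allowed for leader peptides; never renumbered).
Parsing resolves identity codes so each stored cell is explicit.

Queries resolve an allele to a row by reducing to 2-field and taking the
longest shared field prefix, ties broken by file order; no row sharing the
2-field prefix is an error. When several 4-field rows share a 2-field
prefix, the first match answers — alignments occasionally disagree at
synonymous-level rows, and first-match keeps the result deterministic.
Unknown residues propagate as missing values (the individual becomes
missing for the affected position variables), never as errors, because
real alignments contain incomplete sequences.

Amino-acid variables are created only at positions that actually vary
(at least two distinct non-unknown residues) among the alleles observed
in the dataset; each variable `GENE_pos_res` carries the omnibus group
label `GENE_pos`. On complete calls, residue counts within a position
group sum to exactly 2 per individual.

## Missing-data policy

A single rule covers all transforms: if either allele slot of a gene is
missing (or unresolvable at the requested resolution), every variable
derived from that gene is missing for that individual. This loses the
half-information of single-allele calls but keeps the diploid-conservation
invariant exact and avoids biasing copy counts downward. Multi-gene
ligand groups (Bw4 spans HLA-A and -B) go missing when any of their
covered genes is missing. Divergence for a half-missing pair is missing
rather than computed against the known allele alone. Association fits
drop incomplete rows per variable (not listwise across the scan).

## Grantham divergence

The bundled 20x20 matrix is generated from the physicochemical formula
D(i,j) = 50.723 · sqrt(1.833 Δc² + 0.1018 Δp² + 0.000399 Δv²) over the
published composition/polarity/volume values, rounded to integers; a few
cells differ by ±1 from the historically printed table because the scale
constant was itself rounded. The matrix is symmetric with zero diagonal.
Per-gene divergence is the mean of D over region positions, excluding
positions where either residue is unknown or an indel from numerator and
denominator; homozygotes score 0 exactly. Region presets (editable YAML):
the antigen-recognition domain (mature positions 1-182) and the class I
B and F peptide-binding pockets. The synthetic alignments used in tests
cover fewer positions than a real class I molecule; region lists are
intersected with the available positions.

## NK ligands and HLA-KIR interactions

Ligand-group assignment is dictionary-first: Bw4/Bw6 and C1/C2 membership
comes from the allele matching table, not from sequence. The one
alignment-derived step is opt-in: splitting Bw4 copies by the residue at
mature position 80 (Thr → `Bw4_80T`, Ile → `Bw4_80I`), the dimorphism
modulating KIR3DL1 binding. Because a group can span genes, tallies can
exceed two copies in rare genotypes; copy dose saturates at 2 to keep the
0/1/2 contract (carrier status, which drives interactions, is unaffected).
Interaction variables are carrier-level: `1` iff the KIR gene is present
AND the ligand group has at least one copy, missing if either side is
missing; the bundled table lists the validated inhibitory and activating
pairs at ligand-group level (KIR2DL1-C2, KIR2DL2/3-C1, KIR2DS1-C2,
KIR2DS2-C1, KIR3DL1/3DS1-Bw4) and is an editable TSV — gene-dose variants
are expressible through custom dictionaries rather than defaulted.

## Statistical engine

Model templates contain the literal token `term`; the engine substitutes
each variable by renaming its encoded vector to a reserved column and
replacing the token, so arbitrary variable names (`A*02:01`) never meet
the formula parser, and interaction templates (`term:sex`) work
unchanged. Families: linear (OLS), logistic (ML logit; estimates are
log-odds ratios), Cox proportional hazards (Efron tie handling;
log-hazard ratios). The reported coefficient is the term's main effect;
CI level defaults to 95%. Non-converging or separated fits yield flagged
missing-stat rows rather than aborting a scan.

Inheritance encodings map 0/1/2 copies to additive (identity), dominant
(≥1), recessive (=2), overdominant (=1); binary variables admit only
additive/dominant, continuous only additive, and requesting an
inapplicable model is an explicit error. Frequency filters use allele
frequency (copies/2n) for counts — carrier frequency optionally — and
carrier frequency for binaries; continuous variables are exempt.

Hardy-Weinberg: per variable, genotypes are collapsed allele-vs-rest to
(n0, n1, n2); the default 1-df chi-square compares observed to expected
proportions at the estimated allele frequency, and the exact alternative
enumerates heterozygote counts conditional on the rare-allele count
(Levene-Haldane), summing configurations no more probable than observed.
Variables with fewer than two observed genotype classes are skipped and
flagged.

Omnibus tests: per group, the full model adds all group variables minus a
reference level to the covariate-only null; the reference is the most
frequent level, for stable conditioning. Aliased columns are dropped by a
greedy rank check against the null design; df is the design-rank
difference, so collinear residues never inflate the test. Degenerate
groups (single informative level) reduce to a 1-df test and are flagged;
fully constant groups report statistic 0, p = 1.

Conditional search runs in rounds: round r re-scans conditioning on all
prior selections (round 1 is exactly the unconditional scan), then picks
the smallest corrected p under the threshold, ties broken by variable
name. Corrected p is recomputed within each round (per-round
multiplicity). A candidate nearly collinear with a prior pick (|r| >
0.999) is skipped with a warning and the next best considered — this is
what keeps a biallelic gene's complementary allele, or an LD proxy, from
being selected twice in different clothing. Multiple-testing corrections
(Bonferroni, Holm, BH, BY) preserve missing entries and exclude them from
the family size.

## Synthetic data

Generators are pure functions of their configuration (seed included) and
emit the exact file dialects the readers parse. Genotypes draw two alleles
independently from per-gene frequency tables — exact Hardy-Weinberg by
construction, so the HWE test has a true null; an inbreeding-style
`hwe_f` parameter injects excess homozygosity for power experiments. LD
proxies copy the source-allele haplotype indicator with probability r and
redraw otherwise, making the haplotype (and genotype-count) correlation
equal r. Phenotypes follow a generalized linear construction on planted
effects: logistic link (binary), additive Gaussian noise (continuous), or
exponential proportional hazards with uniform censoring (survival).

What this emulates — and what it does not: cohorts are unrelated, alleles
are equilibrium-sampled, genes are independent except for declared
proxies, and effects are additive on the linear predictor. Real MHC data
has pervasive long-range LD, population structure and haplotype effects;
passing tests demonstrate the correctness of the transformations and the
statistical machinery under the stated model, not robustness to
confounding in real cohorts.

Default study conditions used by the test-suite and the acceptance
script: planted-effect recovery uses a log-odds ratio of log 2 at allele
frequency 0.2 in cohorts of 2000 (200 and 100 replicates respectively);
Hardy-Weinberg calibration uses 2000 null cohorts of 500; conditional
recovery plants log 2.5 and log 1.8 effects at frequency 0.25 with a
0.95-correlated proxy in cohorts of 2000; the fine-mapping workflow uses
500 individuals over six DQB1 alleles with F/Y/L variation at position 9.

## Numerical and interface choices

- Likelihoods and coefficients come from statsmodels; Cox fits from
  lifelines. Tests verify engine outputs against independently scripted
  refits (raw-array statsmodels calls; Cox against a second
  implementation) to 1e-6 relative tolerance.
- Result tables have a stable column order and fixed decimal formatting
  (scientific below 1e-4); reruns with the same config and seed are
  byte-identical.
- Ties in p-value sorting fall back to nominal p, then variable name
  (stable mergesort), so output order is deterministic.
- `run.log` echoes the full effective configuration and seed; it contains
  input paths, so logs from runs in different directories differ even
  when results are identical.

## Known limitations

- KIR copy number and KIR allelic variation are not modelled; gene
  presence only.
- Haplotype inference and haplotype-level tests are out of scope.
- Population reference frequencies must be supplied as a local table;
  there is no online retrieval.
- Bundled dictionaries are starter fixtures pinned to common alleles, not
  a substitute for release-matched tables in production analyses.
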