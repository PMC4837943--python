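# Methods

## Mass calculus

Every lipid species is modelled as a diacylglycerol: glycerol
(C3H8O3) + head-group residue + two acyl chains as free acids
(C_n H_(2n−2d) O_2) − two esterification waters. Head-group residues
(elements added to the diacylglycerol, net of condensation water):

| class | residue | note |
|-------|---------|------|
| MGDG  | C6H10O5  | one anhydro-hexose |
| DGDG  | C12H20O10 | two |
| TGDG  | C18H30O15 | three |
| SQDG  | C6H10O7S  | sulfoquinovose |
| DGCC  | C6H11NO3  | carboxy-(hydroxymethyl)-choline, ether-linked |
| PC    | C5H12NO3P | phosphocholine |
| PE    | C2H6NO3P  | phosphoethanolamine |
| PG    | C3H7O5P   | phosphoglycerol |

Masses are monoisotopic (ion-trap annotation convention) computed via
`pyteomics.mass`; adduct m/z uses proton/sodium/ammonium/acetate shifts
corrected for the electron. Consistency anchor: MGDG 18:3/18:3 =
774.5282 Da (the commercial standard), and the sodiated DGDG 36:9 ion at
m/z 953.5 loses its 18:5 and 18:4 acids to the fragments near m/z 679
and 677 — the textbook galactolipid regiochemistry experiment.

Species masses depend only on the sum composition, so chain order (or
absence) never changes an m/z. The default chain alphabet
{14:0, 16:0, 16:1, 18:0, 18:1, 18:3, 18:4, 18:5, 20:5, 22:6} covers the
chains reported for freshwater dinoflagellates; it is configurable.

## Shipped library

`data/lipid_library.tsv` reconstructs a dinoflagellate membrane-lipid
inventory (9 MGDG, 13 DGDG, 10 TGDG, 9 SQDG, 29 DGCC, 19 PC, 3 PG,
3 PE). The dominant species (36:8/36:9/36:10 and 38:9/38:10
galactolipids, DGCC/PC 36:6, 38:6, 44:12, SQDG 34:1, PE 32:1/34:2, …)
are literature-attested; the remaining entries are plausible
compositions over the default alphabet. The inventory and its preferred
adducts (galactolipids [M+Na]+; DGCC/PC [M+H]+; SQDG/PE/PG [M−H]−) were
chosen so that all theoretical candidate m/z within one polarity are
≥ 0.4 Da apart: the annotation rules emulate a workflow whose purpose is
unambiguous species assignment at unit resolution, so the packaged
library is constructed to be annotatable. Known betaine/phospholipid
isobars (e.g. protonated PC C:D vs DGCC C+2:D+4, Δ ≈ 0.013 Da) are
therefore represented by only one partner of each pair.

One nomenclature wrinkle: the 16:0/22:6 betaine species sums to 38:6 and
is stored as DGCC 38:6; DGCC 36:6 is the 14:0/22:6 species.

## Annotation

MS1 matching compares each peak against every (species, preferred
adduct) m/z for the peak's polarity within ±0.3 Da (unit-resolution ion
trap; configurable); all candidates are kept, ranked by |error|.
Retention time is carried but never used (chromatography is out of
scope — a documented limitation).

MS2 assignment enumerates the chain pairs compatible with the
candidate's sum composition and predicts, per chain, the acid and the
ketene (acid − H2O) neutral-loss fragments, plus a per-class calibratable
loss offset (default 0; the mechanism exists because some betaine
fragmentations print fragment m/z that plain acid/ketene arithmetic does
not reproduce). The pair with both chains matched at smallest summed
error wins. For MGDG/DGDG/TGDG the chain whose loss fragment is more
intense is placed at *sn*-1; an intensity tie (within 1% relative)
leaves the order unresolved, because the rule is an inequality, never a
coin flip. DGCC/PC pairs are always reported unordered. Quantification
uses only each class's quantification polarity (positive: MGDG, DGDG,
TGDG, DGCC, PC; negative: PE, PG, SQDG); species seen only in the other
polarity are flagged and excluded.

## Quantification and indices

Relative areas are within-class fractions (0–1) internally; percentages
appear only at reporting layers — the UI magnitudes (≈9 for a
36:9-dominated class) are only consistent with fraction weighting.
Not-detected cells are zeros with a detection mask and enter all
downstream statistics as 0. UI and ACL are convex combinations, hence
bounded by the class's min/max double bonds and carbons. The
galactolipid ratio is reported in [DGDG]/[MGDG] orientation (values > 1
for DGDG-dominant taxa) and multiplied by the internal-standard factor
F; F defaults to 1 when no standard pair is supplied, since the factor
is instrument-specific.

## Multivariate models

Preprocessing is log10(100·x + 1) on the percentage scale followed by
Pareto scaling (centre, divide by √sd) — log base and scale follow the
common chemometric-software convention. Zero-variance columns are
dropped with a warning.

PCA is plain SVD with per-component R²X and a deterministic sign fix
(largest-|loading| element positive). PLS-DA is sequential NIPALS PLS1
on the centred 0/1 class code, 2 components by default. Q² =
1 − PRESS/SS from 7-fold venetian-blind cross-validation (folds dealt
round-robin over the class-sorted sample order, which keeps both classes
in every training set when each class has ≥ 2 members). Permutation
significance refits the full CV under label permutation and uses the
(1+b)/(1+m) estimator (m = 200 by default), which can never return 0.
OPLS-DA removes `n_orthogonal` (default 1) orthogonal components before
a single predictive component; p(corr) is the Pearson correlation
between the predictive score and each (preprocessed) variable. Markers
require |p(corr)| ≥ 0.75 and two-tailed Welch p < 0.05 (Satterthwaite
degrees of freedom; both groups constant and equal ⇒ p = 1).

Pipeline group labels default to the sign of PCA axis 1 (groups are
discovered unsupervised, then supervised), with the lexicographically
first group on the negative side — a cosmetic convention.

## Concordance

Genetic distance is the uncorrected p-distance with pairwise deletion
of gap/N sites; a pair with no comparable sites is an error. The Mantel
test correlates upper-triangle entries and permutes rows+columns of the
second matrix jointly; significance is one-tailed on r ≥ r_obs by
default (positive concordance is the hypothesis), two-tailed by flag.
For n ≤ 6 taxa all n! permutations are enumerated exactly.

NMDS minimises Kruskal stress-1 by alternating isotonic regression of
embedded distances on the dissimilarity ranks with Guttman-transform
updates, from a classical-scaling start plus 4 random restarts (best
kept). The Shepard diagnostic pairs the embedding distances with the
same dissimilarity used for the embedding (mixing in a different
dissimilarity for the diagnostic would make the stress incoherent);
stress < 0.2 is the conventional adequacy threshold.

Ward clustering uses 1 − Pearson r between taxa profiles, converted to
√(2(1−r)) so the linkage operates in Ward-compatible squared-Euclidean
geometry (raw 1−r mode available). Bootstrap support is the plain
bipartition frequency over B variable-resamples (default 1000);
multiscale-AU correction is out of scope. Leave-one-taxon-out Mantel
diagnostics flag single-taxon-driven correlations.

## Synthetic data generator

The generator emulates a ten-taxon, two-group study (4 vs 6, the
C18/C18 vs C20/C18 clusters). Within-class compositions are Dirichlet
draws (concentration 50) around group templates whose marker magnitudes
follow the published group means (e.g. DGDG 36:9 at 80% vs 7.5% of the
class); Dirichlet noise respects the sum-to-one structure the analysis
assumes — Gaussian noise would not. MS1 peaks sit at theoretical adduct
m/z with Gaussian noise; MS2 fragments are acid losses with a planted
sn-1:sn-2 intensity ratio (default 1.7). Alignments are 606-nt
two-clade simulations with disjoint stem-substitution sites and private
per-taxon substitutions.

What the generator does **not** emulate: chromatographic peak shape and
retention behaviour, isotope envelopes, in-source fragmentation,
between-class response differences, or phylogenetic signal beyond a
two-clade topology. Passing tests therefore demonstrate correctness of
the statistical machinery on data with the assumed structure, not
instrument-level robustness.

Because compositions close to 1 within each class, every species in a
class that contains a planted marker is genuinely differential (its
residual share differs between groups); only the marker-free classes
(PC, PG) provide template-identical null variables. Recovery
experiments count false discoveries against those nulls.

## Problem sizes and numerical choices

Statistical calibration suites in the test battery use: 200 null
datasets × 99 permutations for the PLS-DA type-I error (at m = 99 the
(1+b)/(1+m) estimator makes P(p ≤ 0.05) exactly 0.05 under
exchangeability), 500 OPLS-DA null fits, 400 Mantel null runs × 199
permutations, 20-seed marker-recovery experiments, and B = 1000
bootstrap replicates; package defaults remain 200 permutations
(PLS-DA), 999 (Mantel) and 1000 (bootstrap). All random draws use
numpy's PCG64 generator under explicit seeds; PCA is seed-free and all
estimators reproduce bit-identically under a fixed seed and input order.
Mass comparisons use 1e-4 Da; intensity ties use 1% relative; class-sum
validation uses 1e-9.

## Known limitations

- Regiochemistry is resolved only for galactolipids, and only through
  relative fragment intensity; co-eluting isomers are not modelled.
- Absolute (molar) quantification and response-factor estimation are
  out of scope; between-class comparisons are only meaningful through
  the ratio/percentage layers.
- The Mantel/NMDS stage consumes an existing alignment; alignment
  construction and model-corrected distances (JC, K2P) are upstream
  concerns.
- With n = 10 samples, Q² and permutation p are honest but
  low-resolution; marker p-values are unadjusted for multiplicity, as
  is conventional for the p(corr)+Welch double filter.
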