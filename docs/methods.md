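# Methods

## Problem and model

`encap` classifies short peptides (8–14 residues, 20-letter alphabet)
into tumor T cell antigens (TTCAs, label 1) versus non-TTCAs (label 0).
The approach is deliberately model-agnostic about biology: no MHC-binding
prediction, no structural features — only sequence-derived numeric
descriptors, feature selection, and ensemble classifiers. The underlying
assumption is that immunogenic peptides differ from non-immunogenic ones
in composition and physicochemical profile (hydrophobicity,
amphiphilicity, charge), which the evaluation battery probes directly via
property-stratified MCC.

## Feature registry

The default registry comprises **57 feature types totalling 4349 values**
per peptide. Several type sizes are fixed by their definitions (AAC 20,
DPC/DDE 400, CTriad 343, GAAC 5, GDPC 25, CTDC/CTDT 39, CTDD 195) or by
the sizes the registry is specified to reproduce (QSO 46 ⇒ nlag = 3;
MSW/Ez/Cougar 30 and Z5 75 ⇒ 10 and 15 summary statistics per scale
dimension). Where a published parameterization was not recoverable, the
registry defaults were chosen once to satisfy those size constraints and
are configurable per encoder:

| block | types | sizes |
|---|---|---|
| AAC, DPC, DDE, CTriad, GAAC, GDPC | 6 | 20+400+400+343+5+25 |
| CKSAAP gap 0–5 | 6 | 6×400 |
| CKSAAGP gap 0–5 | 6 | 6×25 |
| CTDC, CTDT, CTDD | 3 | 39+39+195 |
| APAAC (λ=3, w=0.05), QSO (nlag=3, w=0.1) | 2 | 26+46 |
| DDR, RRI, SER, SEP | 4 | 20+1+1+14 |
| scalar globals | 10 | 10×1 |
| MSW, Z3, Z5, Ez, Cougar, ABHPRK | 6 | 30+30+75+30+30+6 |
| OVPC class fractions | 14 | 14×1 |

Conventions that matter:

- **Frequencies** are raw counts over the number of windows (L, L−1 or
  L−k−1); no pseudocounts. Every compositional block sums to 1.
- **DDE** standardizes dipeptide frequencies against expectations from
  the 61 sense codons of the standard genetic code:
  Tm = (C_i/61)(C_j/61), Tv = Tm(1−Tm)/(L−1), DDE = (Dc−Tm)/√Tv.
- **CTD** uses 13 three-class physicochemical partitions (seven
  hydrophobicity scales, van der Waals volume, polarity, polarizability,
  charge, secondary structure, solvent accessibility). CTDT counts
  class-changing adjacent pairs divided by L−1 (the field's convention;
  the per-property transition block therefore sums to the fraction of
  class-changing pairs, not to 1). CTDD reports percent positions of the
  first/25%/50%/75%/last occurrence of each class, 0 for absent classes.
- **APAAC/QSO** couple residues at sequence offsets via standardized
  hydrophobicity/hydrophilicity scales (APAAC) and two squared-distance
  matrices (QSO). With λ = 0, APAAC reduces exactly to normalized AAC.
- **Scale descriptors** summarize the per-residue profile of each scale
  dimension with order statistics (mean, std, min, max, median,
  quartiles, first, last, range; the 15-statistic mode adds terminal and
  3-window summaries). All statistics are defined for every length ≥ 3,
  so no encoder silently pads.
- **Scalar globals**: length, molecular weight, Henderson–Hasselbalch net
  charge at pH 7 (EMBOSS-like pKa set), charge density, isoelectric
  point, instability index, aromaticity, Ikai aliphatic index
  (X_A + 2.9 X_V + 3.9 (X_I + X_L), mole percents), Boman index
  (negated mean water→cyclohexane transfer energy), hydrophobic ratio.
  Molecular weight, instability and aromaticity are delegated to
  Biopython's ProtParam. The isoelectric point is the root of
  Biopython's Bjellqvist charge function found by bisection over the
  full 0–14 pH range, because ProtParam's own search clamps its interval
  at [4.05, 12] and mis-reports very acidic short peptides.

### Residue tables

Published tables the package pins with citations: Hellberg z-scales
(z1–z3), Hopp–Woods hydrophilicity, the classical APAAC normalized
hydrophobicity, Kyte–Doolittle hydropathy, Radzicka–Wolfenden transfer
energies, Grantham's composition/polarity/volume triples (the 20×20
distance matrix is recomputed from its closed form with the mean
off-diagonal normalized to 100). The multidimensional MSW, Ez and Cougar
scales, dimensions 4–5 of the five-dimensional z-scale, and the
sequence-order distance matrix paired with Grantham's are **constructed
synthetic stand-ins** (standardized combinations of the published
properties above, documented in `tables/scales_synthetic.py`). They
preserve dimensionality and scaling behaviour but not literature values;
every test and acceptance check treats the tables as opaque pinned data,
so results characterize the pipeline, not those particular scales.

## Normalization and feature selection

Robust scaling is per-feature (x − median)/(Q3 − Q1) with quartiles by
linear interpolation between order statistics; zero-IQR features divide
by 1, so constants center to exactly 0. Scaler parameters are always
fitted on training data and reused downstream (the inverse transform is
exact to machine precision).

Ranking is the shadow-feature (Boruta) procedure: per iteration, append
a shuffled copy of every undecided feature, fit a 200-tree random forest
(depth ≤ 7), count a "hit" for every real feature whose importance
exceeds the best shadow importance, and decide via two-sided binomial
tests at α = 0.05 with Bonferroni correction over the undecided features
(the canonical defaults; the procedure is deterministic given a seed).
The final order is decision tier (confirmed ≺ tentative ≺ rejected),
then mean importance, then name — so ties are reproducible. An optional
zero-variance filter can drop constant columns before ranking (off by
default; a full encoding of short peptides typically carries a handful
of constant features, which is why the number of *ranked* features can
sit slightly below 4349).

The subset search evaluates top-N prefixes (grid default
N = 50, 70, …, 410; reduced grids like {20, 40, 60} are used in
quickstart fixtures for speed) with stratified 5-fold CV under each
ensemble family at implementation defaults, records MCC per (N, family),
takes the per-N maximum across families, and returns the smallest N
attaining the overall maximum. Prefixes are nested by construction. By
default the CV inside the search re-fits the scaler on each training
fold (leakage-safe); `paper_mode` instead normalizes once on the whole
CV set, matching the flowchart ordering of the original two-stage
design.

## Models and optimization

All seven families run single-threaded and seeded. Stage-2 optimization
is an in-package univariate tree-structured Parzen estimator: trial 1
always evaluates the family defaults, trials 2–10 sample the declared
space uniformly, and later trials model the top-25% trials against the
rest with Gaussian/categorical Parzen windows, proposing the candidate
(of 24 draws) maximizing the good/bad density ratio. The objective is
mean 5-fold CV MCC; 10-fold CV is reserved for reporting. Search spaces
are standard per-family ranges declared in `models.SEARCH_SPACES`.
Early stopping is disabled everywhere. The stage-2 design matrix is the
deployment representation (scaled selected features + unscaled motif
bits), so CV inside optimization uses it as-is rather than re-scaling
per fold; this keeps the optimized objective consistent with what the
deployed bundle computes. After optimization the model is refit on the
entire CV set — the independent-test protocol, which trains on ~10% more
data than any CV fold model.

Motif features are exact-substring presence bits over plain consensus
strings (3–20 residues), positives first then negatives, duplicates
across classes kept as distinct bits. Position-weight-matrix scanning is
a documented alternative that this implementation does not attempt,
since the consumed motif lists are plain strings with no score model.

Class imbalance is left untouched (no resampling, no class weights); the
decision threshold is 0.5, inclusive on the positive side, and
configurable per bundle.

## Synthetic data

The generator samples residues i.i.d. per position from class-conditional
weights, lengths uniform on 8–14. The default strong-signal condition
down-weights hydrophobic residues (V,I,L,M,F,W,C) in positives to 0.3×
and enriches hydrophilic ones — an idealization of the compositional
bias real antigen corpora show. `plant_motif` substitutes a motif at a
random valid offset in a configurable fraction of one class. Because
positions are independent, the generator has analytically known
composition statistics (used by the law-of-large-numbers tests), but it
reproduces none of the positional, MHC-anchor or homology structure of
real peptides: passing the recovery tests demonstrates that the pipeline
detects compositional and motif signal at realistic sample sizes, not
that it attains any particular accuracy on real antigen data.

## Problem sizes and numerical choices

The test and acceptance battery runs at deliberately reduced scale so a
full pass stays in minutes on one CPU: pipeline-level checks use a
10-type registry (~130 features), 100–200 training peptides, 3-fold CV,
10 shadow-ranking iterations and 1–2 optimization trials; the
planted-recovery check uses 5 informative + 100 noise features at
n = 500 over 10 seeds; the null-signal check reports the median held-out
MCC over 10 seeds. Tolerances: scaler invariants at 1e-10 (median/IQR)
and 1e-12 (inverse round-trip); oracle comparisons at 1e-10 elementwise.
MCC with any zero marginal is defined as 0. AUC is the tie-aware
rank-sum statistic. Degenerate inputs are errors, not silent defaults:
single-class labels, classes smaller than the fold count, grids larger
than the feature list (truncated with a warning), peptides shorter than
an encoder's minimum (full registry: 7, set by CKSAAP at gap 5).

## Known limitations

- The CB (CatBoost) family activates only when its backend is installed;
  otherwise it reports itself unavailable and the remaining families
  carry the battery.
- Constructed stand-in scales (above) mean MSW/Ez/Cougar/Z5/QSO-block
  values are not comparable to encodings produced with the literature
  tables, though all structural behaviour is identical.
- Exact-substring motif matching cannot express degenerate consensus
  positions.
- The synthetic generator's i.i.d. assumption understates the difficulty
  of real TTCA discrimination; benchmark-grade accuracy claims require
  the external benchmark corpora, which this package treats as optional
  user-supplied inputs.
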