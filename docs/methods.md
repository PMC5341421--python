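# Methods

## Scope and data model

The package analyzes amino acid substitutions in the 13 polypeptides encoded
by the human mitochondrial genome (rCRS, NC_012920.1). Its inputs are (i)
aligned-FASTA ortholog alignments with one designated human reference row,
(ii) a TSV partition of each polypeptide's residues into intermembrane (IM),
transmembrane (TM) and matrix (M) domains, and (iii) TSV tables of labeled
variants with curation evidence. It does not retrieve sequences, build
alignments, or infer domain boundaries — those are upstream of the artifact,
and the domain TSV is a user-editable input rather than a claimed set of
coordinates. All alignment-derived quantities are expressed in reference
residue coordinates through a column map built by scanning the reference row
and skipping its gap columns.

Residue symbols outside the 20-letter alphabet (X, B, Z, J, U, O, …) are
pooled into an "unknown" bin that counts toward the column total but never
toward any residue, so ambiguous database entries can only dilute, never
inflate, conservation. '-' and '.' both read as gaps; case is folded.

## Genetic code and enumeration

Translation uses NCBI table 2 (AGA/AGG stop, TGA = W, ATA = M). Gene models
handle the two mitochondrial peculiarities explicitly: a trailing 1–2 nt
remainder of a CDS is treated as an incomplete, polyadenylation-completed
stop codon and excluded from the protein, and codon 1 is read as methionine
whatever its genomic sequence. Exhaustive enumeration visits the 9
single-nucleotide neighbors of every protein codon and keeps those encoding
a different standard residue; stop-gain and stop-loss events are excluded
because the object of study is amino acid replacement. Neighbors of codon 1
are classified against the translated protein (whose first residue is M).
Each variant carries its rCRS nucleotide event; MT-ND6, the only L-strand
gene, gets complemented bases and reversed coordinates. Counts can be
reported per nucleotide event or collapsed to distinct amino acid changes
(two events at one codon can produce the same replacement, e.g. ATA→CTA and
ATA→TTA are both M→L); reconciling a genome-wide total against an externally
reported figure requires the actual rCRS coding sequences as input and a
choice between these two conventions, which is why both are exposed.

## Feature 1: conservation plus coevolution

CI(i) is the percentage of rows carrying the reference residue at position
i; gaps and unknowns stay in the denominator. Coevolution is measured with
a mutual-information network rebuilt from first principles, since the
original score this emulates came from a web service whose internals are not
recoverable; every ingredient is therefore a documented, configurable
choice:

- MI per column pair from plug-in (empirical) entropies in bits, tabulated
  over the rows where both columns carry a standard residue;
- average-product correction (APC(i,j) = m<sub>i</sub>m<sub>j</sub>/m, means
  over off-diagonal entries) subtracted by default to suppress phylogenetic
  and depth background (`correction="none"` disables it, and then the
  diagonal holds each column's own entropy);
- pairs retained for the cumulative score when the z-score of their
  corrected MI over all pairs of the polypeptide exceeds 6.5, the
  conventional high-confidence cutoff for this construction (`z_threshold`
  is a parameter; `None` retains everything);
- cMI(i) = sum of retained scores involving i, min-max rescaled to [0, 100]
  within the polypeptide. A degenerate scale (all positions equal) maps to
  0 everywhere with a warning rather than dividing by zero.

F1 = CI + cMI<sub>rel</sub> ranges over [0, 200]. No sequence weighting or
identity clustering is applied by default — rows are counted as given, the
simplest reproducible convention; plug-in MI is biased upward at small
depth, which the APC largely absorbs and which vanishes for the ~5,000-row
alignments the pipeline targets.

## Feature 2 and Feature 3

F2 is the mutant residue's percentage at the position, same denominator as
CI; F2 of the reference residue equals CI by construction. F3 pools, per
domain, the observed-symbol counts of every reference position across the
13 alignments into a 20×21 table (wild-type residue × observed symbol), then
renormalizes each wild-type row over mutant residues only — the diagonal
(conservation of the wild type) and the gap column are excluded — so a row
sums to 100 % across specific replacements. Pooling sums raw counts, the
maximum-likelihood estimate of the domain-conditional substitution
distribution, in which deeper alignments weigh more; `pooling="mean"`
instead averages per-position frequency vectors, weighting positions
equally. Per-domain composition reports (residue counts, percentages, mean
CI) define the domain CI of a residue as the unweighted mean of per-position
CIs over the positions carrying it — the pooled-frequency alternative is
equally defensible but less interpretable position-wise.

## Curation and split

A variant is damaging only if disease-associated and either functionally
confirmed (cybrid / single-fiber evidence) or rare in the strong sense:
more than one affected pedigree, carrier frequency ≤ 0.1 ‰ (boundary
inclusive), and absent from internal branches of a phylogeny. Missing
evidence fields fail their criterion and are logged. The train/validation
split is stratified per label with round-half-up of fraction × n, so the
canonical corpus (57 damaging / 2,778 neutral) splits 34/23 and
1,667/1,111 at 60/40. (The originating study reports 1,701/1,077 neutrals,
which no per-label rounding rule reproduces; the damaging 34/23 split does
reproduce. This package follows the stated rule rather than imitating the
irreproducible count.)

## Classifier

Min-max normalization is fit on the training partition only; transformed
validation values are deliberately not clipped, so out-of-range inputs
remain visible. SMOTE is implemented in-package: each synthetic sample
interpolates attribute-wise between a random minority seed point and one of
its k = 5 nearest minority neighbors, each attribute independently uniform
within the closed interval — hence synthetic points never leave the
per-attribute envelope of the minority class — and the damaging class is
raised to parity with the neutral class. Grid search over
C ∈ {2⁻⁵ … 2¹⁵} and gamma ∈ {2⁻¹⁵ … 2³} (powers of four by default,
bracketing the published operating point C = 200, gamma = 0.01) uses
stratified 10-fold CV with normalization and SMOTE re-fit inside each fold
on the training folds only, preventing synthetic-sample leakage into fold
evaluation. Selection maximizes mean balanced accuracy — appropriate when
the minority class is the clinical concern — with ties broken toward
smaller C, then smaller gamma. The final model refits on the full
SMOTE-balanced training set; prediction is the SVM sign, with no
probability calibration and no abstention. Models serialize to a versioned
JSON recording C, gamma, normalization, SMOTE parameters and training data,
and are re-fit deterministically on load.

Evaluation uses confusion counts with damaging as the positive class;
external predictors that abstain have their "unknown" outputs mapped to
neutral (configurable) before counting. Sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP), reported to one decimal; feature values are
reported to two decimals with full precision available on request. Group
comparisons use the two-sided Mann–Whitney–Wilcoxon test, exact for small
tie-free samples and tie-corrected normal approximation otherwise.

One published benchmark cell is internally inconsistent: the validation
specificity printed as 58.7 for the mtDNA-specific classifier does not equal
TN/(TN+FP) = 623/1077 = 57.8 from its own printed counts, and a second cell
(1646/2778) rounds to 59.3 where 59.2 was printed, apparently truncated.
The package recomputes all metrics from counts and treats those two cells
as documentation, not targets.

## Synthetic data

The alignment generator draws i.i.d. rows given column parameters: the
reference residue with probability p_i, otherwise a background residue;
selected column pairs instead follow a two-state symmetric joint
distribution whose coupling c has closed-form MI = 1 − H₂((1+c)/2) bits,
giving the MI estimator an exact planted truth; gaps are injected at a flat
rate, never into the reference row. It deliberately omits phylogenetic
correlation between rows — real ortholog sets are tree-structured, so real
MI backgrounds are heavier; passing recovery tests here validates the
estimators, not the biological calibration of the retention threshold.

The feature-table generator draws class-conditional truncated normals with
default moments equal to the curated corpus's observed class statistics
(damaging vs neutral: F1 107.9 ± 22.6 vs 80.2 ± 33.8; F2 1.4 ± 5.1 vs
8.2 ± 14.2; F3 9.4 ± 8.8 vs 12.7 ± 8.5; 57 vs 2,778 variants), truncated to
the features' ranges. Truncation is on the distribution, not by clipping,
so recovery tests compare sample moments against the theoretical truncated
moments (material for the damaging F2, whose mass is cut hard at 0). It
ignores the features' real mutual dependence (F1 and F2 share a column),
so pipeline results on it demonstrate that the machinery learns a planted
class difference of realistic magnitude under realistic imbalance — not a
performance claim about real variants. The fixture bundle (three 20-residue
toy polypeptides, 200-row alignments, full annotations, labeled variants)
exercises every reader and the end-to-end CLI in seconds.

## Problem sizes and determinism

The test suite and the acceptance script run the classifier pipeline at the
full curated-corpus scale (2,835 variants) with a reduced grid of 9–16
points around the published operating point; MI networks in tests use
10–60-column alignments with 200–2,000 rows, sizes at which every planted
parameter is statistically recoverable at 3 standard errors. All randomness
(simulation, splitting, CV shuffling, SMOTE) flows from explicit integer
seeds; regeneration is bit-identical per seed.

## Known limitations

- The coevolution score is a faithful reconstruction of a published network
  construction, not a byte-level reproduction of the original server; real
  per-variant F1 values from the original study are therefore reference
  points, not test oracles, without the original ~5,000-species alignments.
- No phylogenetic weighting anywhere: deep, redundantly sampled clades pull
  both CI and substitution tables toward themselves.
- The classifier's operating point is threshold-free (SVM sign); no
  calibrated probabilities are produced.
- tRNA/rRNA variants, indels and multi-nucleotide substitutions are out of
  scope by design.
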