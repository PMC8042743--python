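# Methods

This note documents the models, rules and numerical choices implemented
in `ntermflow`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one reasonable choice
existed.

## Coordinates and cleavage-site conventions

All protein coordinates are 1-based and inclusive; position 1 is the
initiator Met. A predicted presequence (signal peptide or plastid/
mitochondrial transit peptide) is described by `cleavage_pos`, the last
residue of the presequence, so the predicted mature N-terminus is
`cleavage_pos + 1`. This follows the convention of TargetP-style
predictors, which report the presequence length. Plastid-encoded
proteins are chloroplast-annotated but carry no transit peptide.

## Positional annotation

An observed terminus at `start` on protein P is classified with the
precedence **POS1 > POS2 > CLEAVAGE_WINDOW > UNANNOTATED**:

* POS1 — `start == 1`;
* POS2 — `start == 2` and residue 1 of P is Met (initiator-Met
  excision);
* CLEAVAGE_WINDOW — P has a predicted cleavage site and
  `|start − (cleavage_pos + 1)| ≤ W`. The window is **two-sided and
  inclusive** with default `W = 5` residues, because observed mature
  plastid termini are frequently "ragged", shifted one or two residues
  to either side of the predicted site. The window kind (SP, plastid TP,
  mitochondrial TP) follows the compartment prediction;
* UNANNOTATED — everything else (internal proteolysis, alternative
  starts, secondary processing such as lumenal cleavages, for which no
  predictor output is consumed).

The first three classes are "expected" termini. The signed offset
`start − (cleavage_pos + 1)` is reported whenever a cleavage prediction
exists, regardless of class, which is what the offset histogram
consumes. Precedence resolves rare overlaps (a cleavage window that
reaches position 1–2) in favor of direct start-site evidence.

Peptides that map to several proteins are assigned to the
lexicographically smallest accession and flagged `ambiguous`; ambiguous
termini are excluded from category tallies by default, since protein-
group handling is not part of this package. Candidate intact precursors
are termini of presequence-bearing proteins starting at
`start ≤ cleavage_pos − W` (which includes POS1/POS2); each candidate is
flagged for whether its peptide contains a Lys, because in the
dimethylation scheme an acetylated α-amine takes no label and the
terminus is channel-quantifiable only via a labeled Lys side chain.

## Modification mass accounting

Modifications are stored as signed elemental deltas and their
monoisotopic shifts are computed from IUPAC atomic masses
(H 1.00782503, D 2.01410178, C 12, ¹³C 13.00335484, N 14.00307400,
O 15.99491462): light dimethyl +2×CH₂ (+28.031300 Da), heavy dimethyl
replacing the two amine hydrogens by two ¹³CD₃ (+36.075670 Da), acetyl
+C₂H₂O (+42.010565 Da), pyroGlu −H₂O from Glu (−18.010565 Da) and −NH₃
from Gln (−17.026549 Da). The unit test checks each against an
independently hand-computed dot product at 1e-6 Da.

## Moderated t-test

Per-terminus pooled variances s² with d residual degrees of freedom are
modeled hierarchically as s² ~ s₀²·F(d, d₀). Hyperparameters are
estimated by moment matching on z = log s²: with
e = z − ψ(d/2) + log(d/2), the excess of Var(z) over ψ′(d/2) identifies
d₀ through 2·ψ′⁻¹(excess) (Newton iteration on the trigamma inverse),
and s₀² follows from the mean of e. When the empirical dispersion of
log-variances is at or below its theoretical minimum ψ′(d/2), the prior
is degenerate: d₀ = ∞ and s₀² is estimated by the arithmetic mean of the
variances (unbiased under the degenerate model, exact when all variances
coincide). Moment matching was chosen over marginal maximum likelihood
for transparency and testability; at the feature counts involved
(hundreds to thousands of termini) the difference is immaterial, and the
estimates agree with the reference empirical-Bayes implementation in R
(`limma::squeezeVar`) within 5% on a shared fixture (tested).

The moderated statistic uses s̃² = (d₀s₀² + d·s²)/(d₀+d) with d₀+d
degrees of freedom; d₀ = ∞ reduces to a z-test against s₀² and d₀ = 0 to
the ordinary pooled t-test (both covered by tests). Missing channel
values simply reduce d; a group with fewer than `min_quant_reps = 2`
present values makes the terminus "skipped" with a reason code. No
imputation is performed on the terminome side — identified-but-not-
quantified termini stay unquantified — and no multiple-testing
correction is applied by default (significance = p < α and |log₂FC| > τ
with α = 0.05, τ = 0.58); Benjamini–Hochberg adjustment is available as
an option. Comparisons are pairwise between genotypes; no 3-group linear
model is fitted.

## Proteome pipeline

* **Quantifiability:** keep a protein iff some genotype has
  ≥ `min_quant_reps` (2) present values out of its replicates.
* **Imputation:** per sample column j, missing log₂ cells are drawn from
  N(mean_j − 1.8·sd_j, (0.3·sd_j)²) computed from the observed values of
  that column — the downshifted-normal strategy for left-censored
  missingness in label-free proteomics (defaults are the widely used
  width 0.3 / downshift 1.8 in SD units; both are config fields).
  Columns with < 3 observed values fall back to global parameters with a
  warning. Imputation is deterministic given the seed; with no missing
  values the pipeline is seed-independent (tested).
* **ANOVA/BH:** vectorized one-way fixed-effects F-test across the three
  genotypes; q-values by the step-up rule (cumulative minimum of
  m·p/rank), cross-checked against `statsmodels.multipletests` and a
  brute-force all-cutoffs evaluation.
* **Tukey HSD:** per protein, q_ij = |mean_i − mean_j|/√(MSE/n) with the
  Tukey–Kramer harmonic-mean n for unequal group sizes, compared against
  the studentized-range critical value q(α; k, df). Computing the
  decision from the critical value (one `isf` evaluation per distinct
  error df) rather than per-pair `sf` p-values is exact for the
  family-wise test and orders of magnitude faster, because SciPy
  evaluates the studentized-range distribution by numerical integration;
  per-pair p-values remain available via `compute_p=True`. Flags agree
  with `scipy.stats.tukey_hsd` on random fixtures (tested) and the null
  family-wise error is 0.05 ± 0.01 by simulation.
* **Clustering/PCA:** per-protein z-scores across the 12 samples
  (flat profiles get z = 0), agglomerative clustering with Euclidean
  distance and average linkage cut at a fixed k = 7 (the tree-cut
  criterion is a design choice; height-based cuts are not implemented),
  clusters relabelled by decreasing size; PCA treats samples as
  observations of the z-scored significant set.
* **Pairwise t-tests:** pooled two-tailed by default (Welch optional),
  flags at p < 0.05 per genotype pair. iBAQ-style columns are consumed
  as provided, never recomputed from peptide counts.

## AP-MS stringent filter

"Identified" is operationalized as a non-missing LFQ intensity. The
stringent set requires presence in all bait replicates, absence in all
controls (full absence, not a ratio threshold — the conservative
reading) and a chloroplast annotation supplied as an input column; an
optional minimum unique-peptide count (default 1) is exposed. The
relaxed set needs only ≥ 1 bait replicate. Stringent ⊆ relaxed always;
both are idempotent and order-independent (property-tested).

## Synthetic data

The generators emulate the structure of the motivating experiment: three
genotypes (wild type `wt`, knock-down `mi`, overexpressor `ox`) × 4
replicates; a 3,000-protein database with 20% plastid-TP, 10% mito-TP,
10% SP and 2% plastid-encoded proteins (i.i.d. uniform sequences,
position 1 fixed to Met, cleavage positions uniform in [30, 80]); a
1,300-terminus terminome with category mixture POS1 0.18 / POS2 0.33 /
plastid-TP 0.14 / mito-TP 0.04 / SP 0.04 / internal 0.27 and ragged
offsets weighted {−2: 0.05, −1: 0.15, 0: 0.60, +1: 0.15, +2: 0.05};
per-category acetylation frequencies 0.89 (Pos1), 0.78 (Pos2), 0.27
(mature plastid), 0.0 (SP-processed) — the two remaining categories,
mitochondrial (0.05) and internal (0.125), are set to plausible low
values consistent with "few" acetylated mitochondrial termini and a
minority of acetylated internal termini. Peptide sequences are real
substrings of the toy proteome, so Lys content (hence quantifiability of
acetylated termini) emerges from sequence composition rather than a
separate coin flip. Intensities are log-normal (log₂ location 23,
scale 2; replicate noise SD 0.25 in log₂). The proteome simulator plants
genotype effects on 45% of proteins (half up-in-`ox`, half up-in-`mi`,
|log₂ effect| uniform in [0.58, 2.0]) and applies missing-not-at-random
dropout: a logistic weight decreasing with log₂ intensity, rescaled so
the expected overall missing fraction matches the requested rate (10%
default). The pull-down simulator plants chloroplast interactors present
in every bait replicate and absent from controls, over sporadic
background proteins.

Every generator draws from its own RNG stream derived as
`seed XOR crc32(operation_name)`, so generators are pure functions of
(parameters, seed) and inserting one simulation between two others does
not perturb them (tested).

**What the simulations do not emulate:** spectra, retention times,
peptide detectability beyond the Lys rule, protein-group/isoform
ambiguity from homologous sequences (sequences are i.i.d., so ambiguity
is exercised with crafted fixtures instead), shared-peptide inference,
channel-specific mass bookkeeping, batch effects, or intensity-dependent
variance. Passing recovery tests therefore demonstrates correctness of
the decision rules and calibration of the statistics under the stated
generative model — not robustness to the full messiness of real
MS data.

## Problem sizes and numerical choices

Calibration checks use 10,000 null features for the moderated-t type-I
error, the ANOVA+BH false-discovery fraction and the Tukey family-wise
error; 1,000 replications (n = 500 pairs each) for Fisher-CI coverage at
ρ = 0.7; and 1,000 termini for noise-free annotation recovery — sizes at
which binomial noise is well below the tolerances being checked while
the whole acceptance script still runs in seconds. The trigamma-inverse
Newton iteration runs to a relative tolerance of 1e-8 (≤ 50 iterations).
p-values are clipped into (0, 1]. Zero-variance degenerate inputs yield
t = 0 / p = 1 when the mean difference is also zero. In quantification
TSVs a zero or empty cell means "not quantified" (converted to missing
on read); literal `NaN` text is rejected.

## Known limitations

* The moment-matching hyperparameter estimator can be unstable below
  ~10 features (it warns and proceeds).
* Average-linkage clustering of imputation-heavy data can produce
  singleton clusters; k is fixed rather than chosen by a criterion.
* The annotation module consumes predictor output; it does not predict
  cleavage sites, handle lumenal (secondary) transit-peptide cleavages
  beyond reporting them as unannotated, or model propeptide maturation
  unless an extra annotation source provides the sites.
* Pairwise proteome t-tests default to the imputed matrix; an
  observed-values-only mode is available because zero/missing iBAQ
  averages in candidate tables suggest unimputed testing may be wanted.
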