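# Methods

`tcrtrace` re-implements, as a tested library, a paired scRNA-seq +
scTCR-seq analysis of T cells from a spontaneously diabetic mouse model:
pooled blood and pancreatic-islet samples are quality-filtered, embedded with
a marker-weighted PCA, gated into T-cell compartments on expression
thresholds, resolved into clonotypes from CDR3 amino-acid sequences, matched
between tissues to call infiltrating cells, summarised into clone fates and
within-clone transition graphs, and finally used to train a sparse
classifier of infiltration status. Because the underlying raw data are not
deposited, every stage is exercised against a synthetic cohort generator
with planted ground truth; this note records the models, the defaults and
why, and what the synthetic results do and do not establish.

## Synthetic cohort model (`tcrtrace.simulate`)

**Expression.** Counts are negative binomial via a gamma–Poisson mixture
with one global dispersion `theta = 4` (variance `mu + mu^2/theta`),
followed by independent dropout at rate 0.03. This is the minimal model with
the zero inflation that makes single-marker gating hard in real data. The
defaults were chosen so that a cell's detected-feature count (~300 of 1,200
genes) and CD3e positivity (~96%) sit where the default QC thresholds are
meaningful.

**Markers.** Each panel gene has an "off" mean (ambient background, default
0.03 counts) and an "on" mean `on_scale * fold` (default `2 * 2 = 4`) in
cells carrying its target compartment or state. `fold` is the effect-size
dial the recovery experiments turn (1.5x / 2x / 4x). Housekeeping genes,
Cd3e and five `mt-` genes are always on; the mitochondrial fraction lands
near 2–3%, well under the 10% ceiling, so the mito filter only removes
genuine outliers.

**Compartments and states.** Per-cell compartment labels follow a simplex
with 33% DN by default (the study system's striking feature); maturation
states are drawn per compartment, with SLEC restricted to CD8 and DP mostly
naive. State fractions are a per-compartment simplex because a single global
simplex would plant SLEC-like DP cells, which the biology rules out.

**Clones.** Cells whose TCR is captured (95%) are partitioned into clones;
clone sizes follow a discrete power law `P(s) ~ s^-2.5` truncated at 75,
reproducing the observed long tail (most clones singletons, few above 10
cells). Each clone carries one beta CDR3 and one or two alpha CDR3s (12% of
clones are dual-alpha), drawn as unique `C...F`-framed strings so clone
identity and CDR3 identity coincide exactly — accidental cross-clone chain
sharing is impossible by construction, which is what makes the planted
cross-tissue clones an exact ground truth. A configurable number of clones
(default 50) is planted with members in at least one blood and one islet
sample. Members of planted cross-tissue clones always receive both chains;
other cells fail pairing at rate `1 - 0.92` and then carry a single chain,
exercising the exclusion rule. Gamma-delta cells carry TRG/TRD chains and
can never participate in alpha/beta matching.

**Infiltration program.** Cells of tissue-spanning clones get a 2-fold bump
on ten ubiquitously expressed genes (Ccl5, Nkg7, ... Cxcr6). This gives the
classifier real but imperfect signal: a perfect oracle on these genes
reaches AUC ~0.9 at cohort scale, so the cross-validated model has headroom
to be honest about estimation noise.

**What the generator does not emulate:** transcriptome-wide co-expression,
batch and library effects, doublets, ambient RNA, V(D)J-gene usage biased by
clone identity, and any coupling between disease status and clone structure.
Passing recovery tests therefore demonstrate correctness of the algorithms
under the stated statistical structure, not performance on real libraries.

## Quality control and normalization (`tcrtrace.qc`)

Cell filters run in a fixed order — CD3 positivity (Cd3e > 0 counts),
detected features in [200, 5,000], mitochondrial fraction <= 0.10,
at least one housekeeping gene (Actb/B2m/Gapdh) detected — and each removed
cell is attributed to the first filter it fails, so the attrition table sums
exactly. Genes detected in fewer than 3 retained cells are dropped last. The
mitochondrial cutoff and housekeeping list are not fixed by the source
protocol; 0.10 and {Actb, B2m, Gapdh} are common murine choices and both are
configurable and logged.

Normalization is `ln(1 + 1e4 * c / total)` per entry (CP10K + log1p),
preserving sparsity; a zero-total cell is an error because it cannot occur
after QC. Scaling centers each gene to mean 0, unit variance with `ddof=1`,
clips at ±10, and maps constant genes to zero — matching the conventions of
the standard single-cell toolchains so results are comparable. Cross-sample
integration (e.g. regularized NB regression of library effects) is
deliberately not performed; the sample label is carried through and the
simpler stated normalization is used throughout.

## Marker-weighted embedding and clustering (`tcrtrace.embed`)

T cells lack the between-cluster variance that drives PCA in mixed-tissue
data; an unweighted embedding mixes CD4/CD8/DN cells within clusters. The
embedding therefore multiplies each scaled feature column by a weight
(default 5.0 for panel markers, 1.0 otherwise — the magnitude is not
prescribed anywhere, so it is a config input and is logged) before the SVD.
The feature set is the union of the weighted markers and the 400 most
variable genes; component signs follow the convention that each component's
largest-magnitude loading is positive, making scores reproducible across
runs and cell orderings. A weight of zero is exactly feature exclusion, and
unit weights reduce to plain PCA — both are asserted in tests.

The KNN graph (k = 20, Euclidean in the top 10 PCs, symmetrized by union)
feeds a Louvain-family modularity optimizer (Leiden on the RB-configuration
objective) at resolution 1.5 by default, seeded and therefore deterministic;
labels are re-ordered so label 0 is always the largest cluster. A
brute-force enumeration of all partitions on <= 12 nodes provides the
modularity oracle in tests. No low-dimensional visualization is produced:
downstream logic consumes PCs, clusters and gates only.

## Gating (`tcrtrace.gating`)

The per-gene threshold is the midpoint between the median of the
zero-expression population and the median of the positive population
("linear gate between the median populations"); since the zero population's
median is 0, this is half the positive median. When positives are fewer than
1% of cells — or in `fixed` mode — the threshold is 0.5 exactly. The
gamma-delta gate (Trgv2, the one reliably detected gamma-chain gene) is
checked first and is exclusive; CD8 positivity is an OR over Cd8a/Cd8b1 (the
permissive reading of gating on both genes, justified by their tight
co-expression; AND is available). Cells then partition into
GD / DP / CD4 / CD8 / DN.

Th subsets are called on non-CD8 cells only with a fixed precedence (Treg,
Th17, Th22, Th1, Tfh, Th2, Th9) because the marker combinations are not
mutually exclusive and no precedence is prescribed; first satisfied rule
wins. SLEC-like is Klrg1+ Gzma+ Il7r-; "exhausted" is operationalized as >= 2
of {Pdcd1, Tigit, Ctla4, Havcr2, Lag3} above threshold (configurable — the
source annotated exhausted clusters by hand, so the count rule is this
package's explicit stand-in).

## Repertoire analysis (`tcrtrace.repertoire`)

A clonotype is the pair (sorted alpha CDR3-aa set, sorted beta CDR3-aa set);
cells need at least one productive alpha and one beta chain, and multi-chain
cells match only on full set equality. Matching between tissues needs only a
single shared alpha OR beta CDR3 (no V/J requirement by default; a strict
mode adds it), and is symmetric by construction. An O(n^2) all-pairs
comparison is kept in the package as the oracle and is asserted equal on
every tested cohort.

Clone fate is SLEC_only / Texh_only / mixed / other from the members' state
labels. Transition likelihoods are estimated per clone with more than 3
cells by drawing 100 unordered pairs of distinct cells uniformly (with
replacement across draws); the likelihood of an unordered state pair is the
fraction of draws, averaged over eligible clones, and per-clone likelihoods
sum to 1 including same-state pairs. The exact enumeration over all C(n,2)
pairs is provided alongside as the oracle; the bootstrap is unbiased for it
(checked to 0.01 over 200 seeded replicates) and converges as draws grow.
Edges are labelled same- vs cross-compartment through an explicit
state-to-compartment map.

Epitope annotation is exact string matching of uppercase CDR3s against a
user-supplied VDJdb-style TSV, honouring the reference chain; no snapshot is
bundled because the reference has no canonical frozen version.

## Infiltration classifier (`tcrtrace.classify`)

Logistic regression with the lasso (L1) penalty and a liblinear
coordinate-descent solver, stratified five-fold CV, on log-normalized
expression of a configurable subset (default: gated CD8 cells in blood,
standing in for the blood CD8 effector-memory subset, which in the source is
a hand-annotated cluster set). Regularization is exposed as sklearn's `C`
(default 1.0). ROC/PR curves and AUC/AUPRC are computed only from held-out
predictions, both pooled and per fold (the two summaries differ under class
imbalance, so both are reported); optional disjoint gene batches (contiguous
variance-ranked chunks of 500) are each fit and reported separately.
Importance is the mean absolute coefficient across folds, normalized to the
top gene; the number of nonzero coefficients is checked to be non-increasing
as regularization strengthens. No resampling is applied to the class
imbalance — AUPRC is reported precisely because infiltrating cells are a
minority.

## Problem sizes and the acceptance script

`scripts/acceptance.py` recomputes the pipeline's headline quantities from
scratch at desk scale: the main cohort is the generator default (6 samples x
400 cells, 50 planted cross-tissue clones), and the classifier section uses
a denser cohort (6 x 800 cells, 200 planted clones) so the blood-CD8 subset
holds ~100 infiltrating cells and the five-fold estimate is stable. These
sizes are the package's own choices for a reproducible desk-scale run;
recovery of planted quantities (DN fraction, spanning clones) is the point,
not the magnitudes themselves. The gap between `infiltrating_clones_planted`
and `_detected` is real attrition: QC can remove every cell a clone has on
one side of the blood/islet divide.

## Numerical and degenerate-input conventions

Variable-gene ties break toward the earlier gene identifier (stable sort);
PCA signs are fixed by the largest loading; cluster labels are size-ordered
with ties by original community id; bootstrap pair draws use
`numpy.random.default_rng` seeded from the run seed; all writers emit fixed
`%.8g` float formatting and sorted JSON keys so identical runs are
byte-identical. Empty inputs return empty outputs (empty truth report,
empty transition graph with a warning, empty importance ranking with a
warning) rather than raising, except where a precondition is violated
(zero-total cells at normalization, unlabeled clone members, single-class
classifier subsets).

## Known limitations

Recovery rates quoted by the tests are properties of the synthetic model at
its stated effect sizes; real libraries have correlated noise the generator
omits. The exhaustion call is a marker-count heuristic, not a cluster
annotation. The transition graph is undirected — pair sampling cannot orient
transitions, only associate states within clones. Epitope matching is exact;
one-residue CDR3 variants are deliberately not matched.
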