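# Methods

This note documents the models and procedures `fibi` implements, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Setting

The package targets rivers converted into reservoir cascades, where no
undisturbed site remains to define a reference condition. Reference
values are therefore derived from *historical* (pre-development)
presence/absence records, and the unit of analysis is the trait
percentage: for site *s* and trait *m*, the share of species present at
*s* that carry *m* (species counts, not abundances). Percentages are
kept at full precision internally and rounded to one decimal only in
reports.

## Reference conditions

**Clustering tendency.** Before clustering, the historical 0/1 matrix is
z-scored per species column (population variance; zero-variance columns
are dropped and reported) and the Hopkins statistic is computed:
H = Σr′ / (Σr + Σr′), with r the nearest-neighbour distances of n
probes drawn from the data (distance to the nearest *other* row) and r′
the nearest-neighbour distances of n uniform pseudo-points drawn in the
per-feature bounding box. H ≈ 0.5 indicates no structure; H toward 1
indicates clusterable data. The probe count defaults to ⌈0.3 · rows⌉
clipped to [2, rows − 1], a small-sample compromise at ~12 sites.
Distances are Euclidean, which the z-score step implies. Under the
uniform null the mean of H over 200 replicate datasets sits within
[0.45, 0.55] (checked in the test suite).

**Clustering and group count.** Site assignments come from agglomerative
clustering with average linkage (UPGMA) on distance 1 − Jaccard
similarity of species sets — the conventional pairing for binary
community data; the linkage is configurable. The group count can be
chosen with the gap statistic: within-cluster dispersion
W_k = Σ_clusters D_r / (2 n_r) (pairwise squared Euclidean distances on
the z-scored table), compared against B = 100 uniform reference
datasets drawn over each feature's observed range, selecting the first
k with gap(k) ≥ gap(k+1) − SE(k+1). The gap routine requires a
feature-space table (reference datasets cannot be sampled from a
similarity matrix alone); assignments themselves may come from either
path, and the Jaccard path is the default because the similarity matrix
is the community-ecology object of record.

**Pooling.** Sites in a group share an expected fauna: the union of
their historical species lists. Reference metric values are computed on
the pooled list, not by averaging member-site values — the pooled fauna
is the "expected species set" of every member site.

## Metric screening

1. **Redundancy.** Spearman correlations are computed between
   species-level binary trait vectors (not site-level percentages — the
   trait–trait collinearity of the fauna is what makes two metrics
   redundant). For each pair with |r| ≥ 0.60, the member with the larger
   |r| to the anchor trait (endemism, EF) is removed; exact ties fall to
   a configurable priority drop list, then to candidate order. The
   anchor is never removed.
2. **Discrimination power.** Box-plot overlap of reference vs current
   value distributions, scored IQ ∈ {0, 1, 2, 3}: 3 = disjoint
   interquartile ranges; 2 = IQRs overlap but neither median lies in the
   other IQR; 1 = exactly one median inside; 0 = both inside. Quartiles
   use linear interpolation (type 7). Only IQ = 3 metrics are kept
   (configurable).
3. **Sensitivity.** A metric is sensitive if current − reference has the
   same strict sign at every site; zeros break the trend ("uniformly
   lower or higher" is read strictly). The surviving direction selects
   the scoring formula.

## Scoring and grading

Decreasing metrics score SE1 = C / R_group; increasing metrics score
SE2 = (Max − C) / (Max − R_group), both clipped to [0, 1] (the expected
total, n metrics × 1, and the five-band scale are only coherent if
per-metric scores cannot exceed 1). A site at or better than its
reference scores 1 regardless of Max, which also resolves the
degenerate Max = R_group case that arises when a reference value is the
data maximum.

**Max.** The scaling maximum is not prescribed by the ratio method
itself; the default takes the maximum of the metric over all current
site values and all group reference values, which guarantees SE2 ∈
[0, 1] on the data at hand. The theoretical maximum (100) and a
reference-only maximum are available via `max_rule`.

**Grades.** The 95th percentile of the expected total is read as the
fixed scalar 0.95 × expected (a constant has no distribution; reading it
as the 95th percentile of *observed* totals is available via
configuration). Totals above it are Excellent; [0, 0.95 n] splits into
four equal lower-inclusive bands Very Poor < Poor < Fair < Good, with a
total exactly at the threshold grading Good. The bands partition
[0, ∞) exhaustively. Published site gradings in this study system are
not reconstructible from any reading of this banding rule (sites with
totals above half the expected total printed as 'Poor'); the package
implements the stated rule rather than reverse-engineering the figure.

**Habitat comparison.** Normality per habitat class is checked with a
Kolmogorov–Smirnov test against a normal with sample-estimated moments
(the common applied usage of the KS normality check; with ~6 sites per
class it is indicative, not powerful). Variance homogeneity uses a
two-sided variance-ratio F test at α = 0.05; the t test is pooled-
variance when homogeneity is not rejected, Welch otherwise.

## Connectivity (TRCI / CTP)

The river is a chain (optionally with extra confluences) of segments
with rank-weighted length shares w_i = 2 r_i l_i / L, L = Σ 2 r_i l_i.
For one barrier configuration, RCI_i = 100 w_i Σ_j w_j p_ij with
p_ij the product of barrier passabilities on the unique i–j path and
p_ii = 1 (the self term is included; the j-sum runs over all segments).
Σ_i w_i = 1, so Σ_i RCI_i = 100 when every barrier is passable, and
adding a barrier or lowering any passability never increases any RCI_i.
Passability defaults: 0.00 for complete barriers, 0.25 for barriers
with fish passages, overridable per barrier.

TRCI_i averages RCI_i over the evaluation years; a barrier is active
from its commissioning year inclusive, so pre-dam years contribute the
undammed index — the time average is exactly the "cumulative time
effect" of impoundment. CTP is the dense rank of TRCI (1 = least
connected, ties share a rank), invariant under monotone transforms; the
continuous TRCI is exported alongside because the discretization used
for the ordinal covariate is a modelling choice, not a property of the
index.

## Driver models

The regression forest is a bootstrap ensemble of CART trees (default
1000 trees, ⌈p/3⌉ features per split, minimum leaf size 2, all
randomness from one seed) with explicit out-of-bag bookkeeping, built
so the two randomForest-style importances are computed exactly as
defined: permutation importance is the mean per-tree increase in OOB
MSE when one covariate is permuted among that tree's OOB rows
(reported as a percentage of the overall OOB MSE), and node-purity
importance is the summed SSE decrease of the covariate's splits.
Explained variance is the OOB pseudo-R², 100 (1 − MSE_oob / Var(y));
because definitions differ across software, the leave-one-out R² from
refitted forests is reported separately rather than conflated with it.
The "top four" drivers are those ranked in the top four on *both*
importance measures, with permutation rank filling any conflict.

Covariates: continuous ones are log10(x + 1)-transformed (negative
inputs are an error); the ordinals HT (habitat class 1/2) and CTP pass
through. Response curves for the top drivers are fitted by OLS with the
polynomial degree raised (max 3 — twelve sites cannot support more)
while the incremental term is significant in a nested F test at
p < 0.05; a non-significant linear slope is flagged rather than
suppressed.

## Synthetic scenarios

The generator produces, from one seed, everything the pipeline
consumes: a trait matrix, historical and current occurrence matrices, a
dammed river network, and a covariate table. Defaults emulate the study
design: 12 sites in 8 contiguous faunal groups, a 160-species regional
pool (within the 100–170 range typical of such mainstems), 25 binary
traits, and site disturbance intensities spanning 0.5–1.0 — on a fully
cascade-dammed mainstem every site is substantially disturbed.

**Pool.** Four trait families are mutually exclusive partitions (mouth
position, water column, body form, egg type). Guild structure is
generated through a latent species class — flow-specialist (45%),
tolerant generalist (30%), neutral (25%): vulnerable-guild traits
(rheophily CUF, planktivory PF, endemism EF, migration MIF, specialist
spawning SPF, drifting eggs DRF) concentrate in the specialist class,
still-water (HYF) and eurytopic (EUF) habits in the tolerant class.
This reproduces the guild covariance of real dammed-river faunas
(drifting-egg spawners *are* rheophiles) while keeping every pairwise
trait correlation near or below 0.4 — comfortably under the 0.60
redundancy threshold, so the screen's redundancy stage does not
amputate planted metrics. Prevalences are planted as exact counts
(largest-remainder rounding over a random permutation): the pool is a
fixed regional fauna, so the configured prevalences are the condition
itself, not a sampling expectation. Decoy and mixed-trend traits
(feeding habits CF/OF/HF/FZ) are assigned stratified over the realized
persistence strata, i.e. with exactly zero association to disturbance
response: in a finite pool their random overlap with the
vulnerable-guild union would otherwise drift every site's percentage
the same way and mimic a uniform trend on a trait planted to carry
none.

**Occupancy and persistence.** Each group's pool is a random 80% subset
of the regional pool; each site holds each pool species with
probability 0.92, so within-group historical Jaccard similarity is
high (≈ 0.85) and between-group similarity much lower. The current
survey keeps each species with probability
sigmoid(logit(p0) + d_site · e_species), p0 = 0.85. The species effect
e uses a limiting-factor aggregation: the most severe vulnerable-trait
effect if any is carried (default −5.5), else the tolerance advantage
if a favoured trait is carried (+4), else a small alternating term
(±0.8, parity offset per trait) for the mixed-trend traits. An additive
dot product was rejected after analysis showed tolerance traits rescue
co-occurring specialists and wash out the monotone percentage shifts
the screening stage is defined to detect; ecologically, a species'
response is set by its most limiting requirement. Magnitudes were fixed
by a design-phase power analysis so that planted shifts exceed
assemblage-size sampling noise (≈ 5–7 percentage points per site) at
every site of the gradient; at freeze the exact screening-recovery rate
was 50/50, 49/50 and 48/50 on three independent 50-seed windows, with
median Spearman ρ(total, disturbance) of −0.89/−0.84/−0.87.

**What passing recovery tests shows — and does not.** Recovery
demonstrates that the pipeline's stages detect the structure they are
defined to detect at the study's scale and noise level. The generator
omits observation error in species detection, abundance dynamics,
dispersal, seasonal turnover, and taxonomic misidentification; real
surveys add all of these, so recovery rates here are upper bounds on
field performance, not estimates of it. Exotic-species introduction is
available (off by default) but deliberately minimal. The ordinal
covariates and the network are simulated independently of the
occupancy disturbance except through CTP's construction, so driver-
recovery tests use directly planted covariate–response links.

## Degenerate inputs and tie-breaks

Validation rejects non-binary cells (naming the offending cell),
duplicate identifiers, empty sites, species missing from the trait
table (a hard error — silent drops would bias percentages), barriers on
non-adjacent segments, passabilities outside [0, 1], and constant
responses in driver models (per-metric models isolate such failures).
Cluster labels are renumbered by first appearance so output is stable;
collinear pairs are processed in descending |r| with lexical tie-break;
empty candidate lists produce a warning and an empty report; a site
empty after persistence thinning is redrawn once and then an error.

## Problem sizes used in the shipped checks

Statistical assertions run at the study scale (12 sites, 160 species)
with 50 scenario seeds, 200 Hopkins null replicates, and 300-tree
forests for the recovery loops (1000 trees remain the analysis
default; recovery of a planted top-1 driver is insensitive to the
difference, and the smaller ensembles keep the full recomputation in
the minutes range on one CPU).

## Known limitations

Percentages are species-count based; abundance weighting is out of
scope. The Hopkins statistic as literally described in some sources
(both probe sets drawn from the data) would be ≈ 0.5 by construction;
the standard uniform-reference construction is used. Branching networks
are supported through the path-product formula, but tributary-specific
connectivity indices are not implemented. The forest's percent variance
explained is definition-dependent (OOB vs LOO); both are reported, and
with ~12 observations neither is a precise quantity. Grading bands
follow the stated banding rule; published gradings that contradict it
are not reproduced.
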