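# Methods

## Data model and normalisation

The substrate is a cells × genes UMI count matrix with per-cell metadata
(`cell_id`, `sample_id`, `cell_type`, `is_malignant`). Counts are never
modified; the normalised layer is log2(TPM/10 + 1) where TPM is approximated
by counts-per-million over the provided genes. UMI counts carry no
gene-length bias, so CPM is the standard TPM surrogate; the scale factor is
overridable. Cells with zero total counts get all-zero normalised rows and a
warning rather than NaNs.

QC removes cells with fewer than 200 detected genes or a mitochondrial
count fraction above 5%. Both boundaries are strict as stated: a cell with
exactly 200 genes and exactly 5% mitochondrial counts is retained.
Mitochondrial genes are recognised by symbol prefix (default `MT-`) because
no fixed gene list generalises across annotations, and the 5% rule is
applied to the *counts* fraction (the conventional reading; a detected-gene
fraction would be an alternative the method does not use). Sample inclusion
for drug-combination prediction likewise uses strict thresholds: at least
100 malignant cells and at least 60 T cells.

## Immune score

The per-sample score quantifies the relationship between T-cell
proliferation and immunosuppressive signalling. Per T cell, suppression
activity *c* is the mean normalised expression over the suppression
signature (up-genes minus down-genes when both are given) and proliferation
*p* the same over the proliferation signature. Ordinary least squares fits
p = b₀ + b₁c across the sample's T cells (minimum 10), and the score is
−b₁/SE(b₁), i.e. the negated slope t-statistic. Degenerate suppression
variance yields score 0 with a warning. This is a deliberately simple,
self-contained regression, not a reimplementation of the full T-cell
resilience machinery with its cytokine-signature databases; the
stratification interface accepts externally computed scores so a full model
can be plugged in unchanged.

Stratification: scores ≤ 0 → low; among positive scores the top
floor(0.10·n) of the cohort → high; the remaining positive samples →
middle. Cohorts smaller than 10 get no high tier, because "top 10%" is a
cohort-relative notion; ties at the high boundary break by `sample_id`
order so the call is deterministic. Tiers are invariant to positive
rescaling of all scores.

## Reference transfer

A cluster is represented by the per-gene median (midpoint for even counts)
of its normalised profiles, restricted to genes shared with the panel. The
similarity kernel is the mean of cosine similarity and Spearman rank
correlation computed on the genes most variable across panel lines
(default 300, capped at the shared-gene count) — a consensus of a
magnitude-sensitive and a rank-based measure in the spirit of
cluster-projection tools. Two similarity summaries serve different roles:
the cluster-profile similarity drives the transfer tier, while the maximum
over (cell, line) pairs drives the clustering objective's S(i) indicator.

Transfer tiers on the best profile similarity s*: s* > 0.8 copies the best
line's sensitivity vector; 0.4 < s* ≤ 0.8 uses a similarity-weighted mean
of the top-5 lines (non-negative normalised weights), a transparent
stand-in for model-based refinement that preserves the convex-combination
property; s* ≤ 0.4 yields no response. The boundary values follow the
wording "above 0.8" / "above 0.4": equality falls to the lower tier.

Raw ln(IC50) panels are mapped to sensitivities by 1 − rank-normalisation
per drug across lines, clipped to [0, 1], giving the bounded "higher =
more sensitive" scale the optimizer expects.

## Response-driven clustering

For T malignant cells the admissible resolutions form the open interval
(T/10000, T/2000); the default grid is 25 evenly spaced interior points.
The cell graph is built once — PCA to 50 components (full SVD, so it is
deterministic), k = 20 nearest neighbours, shared-neighbour Jaccard edge
weights — and Leiden community detection (RBConfiguration modularity,
fixed seed) is run per grid point. Any seeded modularity method with a
resolution parameter satisfies the contract; Leiden is used for its
determinism and quality.

Per resolution, J(r) = M(r)/10 + Σ S(i)·cell_number(i)/T with
S(i) = 1 iff the cluster's max cell-line similarity strictly exceeds
α = 0.4. Feasibility requires the transferred response matrix W (clusters
with no transferable response contribute all-zero columns — the
conservative choice for the divergence test) to satisfy
Σ_k Σ_{i>j} (W_ki − W_kj)² > ε = 1, which stops resolution from growing by
splitting clusters into response-identical copies. The best feasible r wins;
ties go to the smallest r (coarsest clustering, for parsimony); if nothing
is feasible the grid point nearest the interval midpoint is returned with a
warning.

## Exhaustion trajectories

Trajectories are defined by start/end cell-type labels (the four defaults:
T_active→T_exhausted, T_memory→T_exhausted, Macrophage→TAM,
Fibroblast→CAF; the mapping is configurable). A trajectory exists when both
endpoints have ≥ 10 cells (an explicit existence threshold, since a ratio
over a handful of cells is meaningless); its score is n_end/n_start, NA
otherwise. No pseudotime graph is learned: the contrast is between the
labelled endpoint populations.

Differential signatures use a two-sided Wilcoxon rank-sum per gene
(asymptotic, tie-corrected) on normalised values, keeping genes with raw
p < 1e-5 and fold change > 2 in either direction; BH-adjusted p-values are
reported alongside but the cut is on raw p, matching how the signature is
defined. Fold change is computed on de-logged mean expression with a
pseudocount of 1, so it is well defined for zero-mean genes.

Reversal scoring builds a ±1 query over the signature genes and returns the
cosine against the *negated* drug signature on shared genes — reversal
mode, because the goal is to oppose the exhaustion programme; a mimicry
drug scores −1. For the bipartite optimizer the scores are rescaled as
(cosine + 1)/2 so trajectory columns live on the same [0, 1] scale as
transferred sensitivities; NA trajectories are dropped, and t_j for a
trajectory column is its end-type cell count.

## Combination optimizer

Group weights C_j = t_j/T + V_j/(M·T); RNA-velocity inflows V_j default to
0 when not supplied. The toxicity flag ε_i is 1 iff a drug has more than
ten side effects with frequency strictly above 30% (both boundaries
strict); drugs absent from the table get 0 — no evidence, no penalty.
R_i sums the cells of groups with W_ij strictly above the response
threshold (default 0.5; this threshold is a modelling choice exposed in the
config, since "responding" is not otherwise quantified on a [0, 1] scale).

The objective as printed contains a coverage term Σ 10·R_i/T that does not
reference the selection; it is interpreted as restricted to selected drugs
— the minimal reading under which the term expresses "selected drugs should
cover the responsive cells" — so

    J(S) = Σ_{i∈S} [ Σ_j C_j W_ij (1 − λ ε_i) + 10 R_i/T ],  |S| ≤ 2.

With at most two drugs the search space is all singletons and unordered
pairs; `solve` enumerates it exactly in O(N²M), ranks candidates by J
descending with lexicographic drug-id tie-breaks, and reports a union
coverage fraction per candidate for interpretation. Antagonism edges
between drugs are not modelled: the scoring formula has no interaction
term, so adding one would be an invention rather than an implementation.

## Evaluation statistics

DCG = Σᵢ rᵢ/log2(i+1) over items ordered by predicted rank, with
rᵢ = |rank_pred − rank_exp|; 0 iff the rankings agree, and disagreement at
the top costs most. Items are ordered by predicted rank (the natural
reading for a prediction-quality metric); tied prediction scores are broken
to strict ranks by drug id (`ranks_from_scores`). Note the reversed ranking
does *not* maximise this statistic in general (a cyclic shift can score
higher); the tests assert relabeling invariance and positivity instead.
The enrichment p-value is the exact hypergeometric upper tail
P(X ≥ k) for k registered combinations among the top tranche M = max(1,
floor(0.10·N)) of N predictions, via `scipy.stats.hypergeom`.

## Synthetic fixtures

The generator emulates the *shapes* and the recoverable signal structure of
the real inputs, not their biology. Default study conditions: 4 samples;
sample S1 is the planted low-tier sample and carries two malignant clusters
of 150 cells each (30 marker genes per cluster boosted 10×); every sample
has 80 scoring T cells; S2 additionally carries active-T-exhaustion
(30 start / 25 end) and CAF-differentiation (30/25) endpoints with a
10-gene block boosted 10× in the end state. Counts are negative binomial
with dispersion 0.5 plus 10% Bernoulli dropout; mitochondrial means are set
so fractions stay inside (0.5%, 3%), i.e. cells pass QC unless dropout
pushes them under the gene floor. The tier signal is a per-T-cell factor f
with log2 f uniform on [−2, 2] scaling the suppression block, while the
proliferation block scales as f^(±1.5) — negative exponent (proliferation
falls as suppression rises → positive score) for middle samples, positive
for the low sample. The 16-fold factor range is what keeps the slope
identifiable above the dropout noise of 8-gene signature means at this
depth. The reference panel's first lines are the log-normalised cluster
means plus Gaussian noise (sd 0.05), each sensitive (0.95) to exactly one
drug with background sensitivities near 0.05, so the planted optimum is the
complementary pair.

What passing recovery tests shows: the pipeline's stages compose correctly
and recover planted signals at realistic desk scale. What it does not show:
robustness to batch effects, doublets, ambient RNA, annotation errors,
continuous (non-block) differentiation, or panels whose lines only
partially match the tumor — none of which the generator emulates.

## Numerical and degenerate-input choices

* Zero-norm or zero-variance vectors contribute 0 to the similarity kernel
  rather than NaN; a constant query profile warns and scores 0 everywhere.
* Wilcoxon p-values that are NaN (fully tied genes) are set to 1.
* All-NA trajectory sets raise with advice to use the cluster pathway.
* Empty drug selections score J = 0; an all-cells-removed QC result is an
  empty matrix with a warning, not an exception.
* Every stochastic step (PCA is deterministic-full-SVD; Leiden, fixture
  generation) takes an explicit seed; fixture substreams are derived from
  `(seed, stream_id)` so components can be regenerated independently.

## Problem sizes

Default test and acceptance runs use the fixture scale above (~700 cells ×
300 genes, 4 lines, 6 drugs), 25-point resolution grids, 100 random
optimizer instances (N ≤ 25, M ≤ 6) for the brute-force equivalence check,
and 10 fixture seeds for end-to-end recovery — sizes chosen so the full
suite exercises every pathway in well under a minute of compute per
component while keeping the planted effects at magnitudes a real dataset
could plausibly show.

## Known limitations

* The immune score is a stand-in regression; absolute score magnitudes are
  not calibrated against any clinical response scale, and single-sample
  stratification requires user-supplied thresholds (cohort-relative tiers
  are undefined for n = 1).
* Sensitivity transfer inherits the panel's coverage: clusters unlike any
  line are ignored, and the refinement tier is a weighted average, not a
  trained response model.
* Trajectory scores compare labelled endpoint counts; mislabelled cell
  types propagate directly.
* The optimizer's coverage term uses per-drug sums over selected drugs;
  drug–drug synergy and antagonism are not modelled.
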