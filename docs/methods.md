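# Methods

This note documents the models and procedures implemented in `stemfc`, the
choices made where conventions were genuinely open, and what the synthetic
testbed does and does not establish about real data.

## Time-series cleaning

Parcellated BOLD series (node × timepoint, dt = 2.5 s by default) are
cleaned per run in the order: nuisance regression → percent-signal-change
scaling → band-pass → per-run demeaning → concatenation. Nuisance regression
is ordinary least squares against a user-supplied design (motion,
physiology, CSF components) plus an intercept; because the intercept
removes the temporal mean, the chain reinstates the raw mean after
regression so the percent-signal-change division stays defined. CSF
regressors are the leading temporal principal components of CSF-voxel
signals (scikit-learn PCA; orthonormal, variance-ordered). The band-pass is
a 2nd-order Butterworth at 0.01–0.1 Hz applied forward–backward
(zero-phase, `sosfiltfilt`); the order and band are configurable. The
per-run stage order is itself a config knob for sensitivity checks.
Whether filtering should precede or follow concatenation is not fixed by
any convention we know of; filtering is per run here, with concatenation
last.

## Connectome construction

FC is the Pearson correlation of cleaned series; the group connectome is
the elementwise mean of subject matrices (raw r, no Fisher transform in the
average). The optional threshold applies a per-edge two-tailed one-sample
t-test to the subject-wise Fisher-z values and zeroes group edges whose p
exceeds the (optionally Bonferroni-divided) α; the surviving-edge fraction
is reported. Weighted degree is the row sum of an FC block with self-edges
excluded. Distance profiles use Spearman correlation of FC against
Euclidean centroid distance within the within-cortex, brainstem–cortex and
within-brainstem pair blocks. tSNR is mean over population (n) standard
deviation, computed before any demeaning; the n vs n − 1 choice is
documented rather than load-bearing (every consumer is scale-invariant).

Atlas utilities threshold probabilistic label volumes at an inclusive
cutoff (a voxel exactly at 35 % is kept), allow overlapping labels,
histogram labels-per-voxel, and parcellate volumes by unweighted in-mask
means (overlapping voxels count for every containing label).

## Signed-modularity communities

The dominant brainstem weighted-degree pattern is regressed (OLS with
intercept) out of each cortical region's brainstem-FC profile; the
brainstem × brainstem similarity network is the Spearman correlation of
residual cortical profiles, diagonal zeroed. Community quality is the
asymmetric signed modularity

    Q(γ) = 1/v⁺ Σ_ij (w⁺_ij − γ s⁺_i s⁺_j / v⁺) δ(σ_i, σ_j)
         − 1/(v⁺+v⁻) Σ_ij (w⁻_ij − γ s⁻_i s⁻_j / v⁻) δ(σ_i, σ_j)

with v± = Σ_ij w±_ij the total (ordered-pair) positive/negative strength.
Sums run over ordered pairs including the diagonal null terms (w_ii = 0 on
input). Two hand-pinned cases fix the normalisation: two disconnected
positive dyads partitioned into dyads give Q = 0.5 at γ = 1 (the classical
all-positive value), and a single positive edge with both nodes in one
community gives Q = 0. γ multiplies both null terms.

Louvain is the standard two-phase greedy scheme on this quality: randomised
node sweeps (seeded), ties broken toward the lowest community index,
aggregation with self-loops, repeated until no merge. Consensus over R runs
follows the agreement-matrix procedure: co-assignment frequencies below
their permutation-null expectation (mean over runs of Σ_c n_c(n_c−1)/n(n−1))
are zeroed and the thresholded agreement network is re-clustered R times,
iterating (cap 100) until all runs agree. Partition stability across runs is
the mean and variance of the pairwise z-scored Rand index under the
hypergeometric model; the resolution sweep covers γ = 0.1 … 6.0 in steps of
0.1 (60 values) by default. Community cortical degree maps sum unregressed
FC over a community's nuclei; per-nucleus community fit is the Spearman
correlation between a nucleus's residual cortical profile and its
community's map (low values flag functionally flexible nuclei).

## Diffusion-map gradients

The cortical similarity matrix (Spearman similarity of residual brainstem
profiles across cortical regions, unit diagonal restored) is embedded by:
row-wise sparsification keeping the top 10 % of entries per row;
normalized-angle affinity 1 − arccos(cos θ)/π between sparsified rows
(non-negative, keeps antipodally organised blocks weakly connected);
α = 0.5 anisotropic normalisation W/(d^α d^α); eigendecomposition of the
Markov operator through its symmetric conjugate; the trivial stationary
component (eigenvalue 1) is dropped and checked to be the largest.
Components are scaled by λ/(1 − λ) (multiscale convention, diffusion time
0) and are defined up to global sign; `orient_gradient` flips a gradient to
correlate positively with a chosen reference. Pole degree maps sum a
brainstem node's FC over negatively and positively scored cortical regions
separately; exact zeros belong to neither pole.

## Dominance analysis

A cortical map is regressed on standardized receptor/transporter maps
(OLS). Dominance analysis fits all 2ᵖ − 1 predictor subsets — R² of each
subset via the centred Gram matrix, so the p = 18 case (262,143 submodels
on 400 observations) runs in seconds — and defines: total dominance of
predictor i as the mean over subset sizes of the mean incremental R² when i
joins a subset of that size (level-weighted averaging, which makes total
dominances sum exactly to the full-model R²; a uniform-over-subsets variant
exists behind a flag but lacks the summation identity); interactional
dominance as the increment when i joins the model containing all other
predictors; percent contribution as total dominance normalised by its sum
(identical under ordinary or adjusted R² normalisation). Ordinary R² is
used for increments, and the full model's adjusted R² is reported
alongside. Term-map profiles report the Spearman correlation of a map with
each z-scored term map; the floor(0.1 T) largest correlations are flagged
(123 terms flag exactly 12), boundary ties broken by term-name order.

## Spin tests

Parcels carry unit-sphere coordinates per hemisphere (each hemisphere is
its own sphere). Each repetition draws one uniform random rotation
(normalised quaternion) for the left hemisphere and applies its mirror
conjugate (F R F, F = diag(−1,1,1)) to the right, then matches original to
rotated parcels one-to-one within each hemisphere by minimising total
squared Euclidean distance (`scipy.optimize.linear_sum_assignment`). The
resulting permutations are cached and reusable across tests. The p-value
permutes one map by every spin, counts null statistics strictly more
extreme than the observed one (two-sided, on |statistic| after de-meaning
both maps), and returns (count + 1)/(R + 1), so p ∈ [1/(R+1), 1]; with
10,000 rotations the floor is ≈ 0.0001. The observed statistic is computed
through the same vectorised code path as the nulls so an identity rotation
ties it exactly. Using a mirrored rotation for the opposite hemisphere
(rather than two independent rotations) preserves bilateral symmetry and is
switchable in principle by generating spins per hemisphere.

## Synthetic cohort generator

The generator emulates a resting-state cohort (default: 20 subjects,
400 cortical + 58 brainstem nodes, 630 timepoints ≈ three 10-minute runs at
dt = 2.5 s, K = 5 communities, 18 receptor maps, 123 term maps) as a linear
latent factor model — the analysis targets are all statements about
low-rank shared covariance, so any generative family with the same first
and second moments would serve. Per subject and timepoint, i.i.d. unit
normal factors g (global), f₁…f_K (community) and h_uni/h_trans (poles)
drive

    brainstem i (community k):  x_i = a G_i g + b f_k + σ_b ε_i
    cortex j:  y_j = a G_j g + α_u Σ_k u_k(j) f_k + v_uni(j) h_uni
               + v_trans(j) h_trans + η_j

with a = 1, b = 0.8, α_u = 0.6; η is spatially correlated cortical noise
with covariance σ_c² exp(−d/decay) (decay 30 mm); known confound loadings
times smooth nuisance regressors are added to all nodes, and node baselines
(cortex ≈ 1000, brainstem ≈ 500) convert the signal to raw scanner-like
units. Noise scales derive from one `snr` knob: σ_b = 8/snr,
σ_c = 1.6/snr, σ_r = 0.6/snr (annotation-map noise), default snr = 2. The
brainstem is deliberately the noisier tissue class, which reproduces the
empirical ordering "mean brainstem–cortex FC exceeds mean within-brainstem
FC".

Planted structure. All planted cortical maps are smooth Gaussian random
fields (exponential kernel, 40 mm) over realistic geometry: two mirrored
hemispheric shells (radius 65 mm) for cortex and a compact midline column
for the brainstem. The map basis (global pattern, axis A, community-private
maps w_k) is QR-orthogonalised in sample so that chance correlations among
smooth maps cannot blur the planted structure; the axis is winsorised at
±2 sd. Community projection maps are u_k ∝ c_k A + 0.6 w_k (standardized),
where the two extreme ("pole") communities take c = ∓3 — their maps are
near-antipodal along A and hold ~30 % of brainstem nodes each — and middle
communities are axis-orthogonal. The planted gradient axis is
standardize(v_trans − v_uni) = A with v_trans = −v_uni = 0.4 A. The
pole-heavy design makes the leading direction of cortical
brainstem-connectivity similarity the axis itself by a wide eigengap, while
pole-vs-pole similarity is strongly negative (which signed modularity
separates cleanly) — mirroring the empirical observation that gradient
extremes dominate and communities align with the hierarchy's poles.
Per-node total variance is equalised within each tissue class by
compensating white noise, so Pearson normalisation scales covariances
uniformly; without this, heterogeneous node variances leak rank-one
structure through the degree regression and distort the similarity
matrices. Receptor maps are Σ_k β_mk u_k + σ_r ε with one strictly dominant
receptor per community; pole-community dominants are planted as cross-pole
contrasts (+1 own pole, −0.5 opposite, 0 middles) because the two pole maps
are nearly collinear and only the contrast coordinate is identifiable.
Term maps are analogous random mixtures.

One global seed fans out to named substreams (structure, annotations,
per-subject counters), so identical seeds give bit-identical cohorts and
enlarging the cohort never perturbs existing subjects.

What the testbed does not emulate: hemodynamic convolution, motion and
physiological artefact structure beyond generic confound regressors,
voxel-level partial-volume effects, inter-subject anatomical variability,
and empirical effect sizes (none are published for this latent structure;
the noise defaults are calibrated only so that planted-structure recovery
is achievable at the stated tolerances). Passing recovery tests therefore
demonstrates correctness of the pipeline's inference under a faithful
low-rank covariance model — not that real brainstem data have this SNR.

Atlas fixtures: Gaussian-blob probabilistic atlases with a requested
overlapping-voxel fraction (realised by bisecting the within-pair blob
distance against the measured overlap at the 35 % threshold) and a
companion 4-D volume whose voxel time series equal the strongest label's
index plus optional noise, so parcel means are predictable exactly.

## Problem sizes and determinism

Default analysis sizes follow the study conditions (458 nodes, 60-value γ
sweep). The test suite and acceptance script run the sweep with 50 Louvain
runs per γ (the stability profile is already flat at 50) and 1,000 spin
rotations for the gradient comparison (the 10,000-rotation floor case is
exercised separately); the full suite runs in ~1.5 minutes and the
acceptance script in ~1 minute on one CPU. Every stochastic step (Louvain
sweeps, consensus, splits, spins, cohort synthesis) is seeded through
`numpy.random.SeedSequence` substreams; reruns with the same configuration
are byte-identical, and pipeline outputs carry a config-hash + seed
provenance sidecar.

## Known limitations

- Louvain returns local optima; on random 8-node signed networks it attains
  the exhaustive optimum in roughly 80 % of single runs (consensus over
  runs is the production path).
- The z-Rand variance formula is undefined for single-community partitions
  (returned as NaN and excluded from sweep statistics).
- The consensus threshold uses the analytic permutation-null mean of
  co-assignment; very flat agreement matrices can collapse to one
  community, which is reported rather than an error.
- Dominance analysis is exponential in predictors and refuses p > 20.
- `distance_fc_profile` treats parcel centroids as points; no geodesic
  correction is attempted.
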