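# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Parcellation model and geometry

An atlas is an ordered list of regions with name, hemisphere
(left/right/midline), compartment (cortical/subcortical/cerebellar),
an optional resting-state network label, and a centroid in mm with x
increasing rightward (input readers must convert if their convention
differs). The "paper-complete" configuration has 333 cortical
(161 left, 172 right), 14 subcortical (7 bilateral structures:
thalamus, caudate, putamen, pallidum, accumbens, amygdala,
hippocampus) and 14 cerebellar regions (7 networks × 2 hemispheres) —
361 in total. Atlases with other counts are accepted and flagged.

**Homotopic pairing.** Each left centroid is reflected across the
midsagittal plane and matched to the nearest right centroid. The
original procedure is a one-directional minimum-distance lookup; we
additionally require the match to be *mutual* (the right region's
mirrored nearest left neighbour must be the same region), which rules
out many-to-one pairings at the cost of excluding a handful of
asymmetric regions. Midline regions never pair: their mirrored
centroid is closest to themselves.

**Bin schemes.** Three equal-width schemes stratify region pairs:
connectivity strength of the normative reference (40 bins of .02 over
[−.2, .6]), structural fiber path length (10 bins of 50 mm over
[0, 500]), and Euclidean centroid distance (33 bins of 5 mm over
[0, 165]). Intervals are left-closed/right-open with the final bin
closed, so boundary values map deterministically; bins with no
reference member are dropped and recorded; reference values outside
the range are excluded and counted, not errors. Self pairs never
participate; strength and Euclidean membership uses the upper
triangle, path-length membership only the structurally connected
pairs.

## QC

Framewise displacement is consumed per volume (the displacement from
volume t−1 to t; the first volume is 0 by convention). A volume with
FD strictly above 0.3 mm is censored together with one volume before
and after (clipped at the boundaries); the one-volume margin follows
standard scrubbing practice, since the source text does not define the
window explicitly. Subjects retaining < 50 % of volumes are excluded.
Censored volumes are dropped, not interpolated, before correlation;
lagged connectivity instead uses the longest contiguous uncensored
run, because gaps or interpolation would distort temporal offsets.

## Connectivity

Zero-lag connectivity is the Pearson correlation over retained
volumes; a region with constant retained signal yields missing values
with a warning, never a silent zero. The primary scale is raw r (the
strength strata span a raw-r range); a Fisher-z transform is available
but off by default. Lagged connectivity computes correlations at
integer-TR shifts out to ceil(lag/TR) + 2 samples, each re-standardized
over its overlapping segment (avoiding attenuation from shrinking
overlap), and interpolates the curve with a natural cubic spline to
the exact evaluation lag (6 s for TR-varied multi-site data, 6.212 s
for a fast-TR replication protocol). Signed lags are kept as separate
features; r(+τ) of pair (a, b) equals r(−τ) of (b, a) by construction.

## Feature families

Per-bin features are the mean of the subject's values over the pairs
in each retained stratum. Homotopic, seed (8 striatal + 2 thalamic
seeds × ipsilateral cortical targets), and network families emit one
feature per pair plus a summary mean. The default-mode set has 41
cortical ROIs; the salience set has 36 (4 salience + 32 dorsal
attention), mirroring the reference parcellation's counts.

**Idiosyncrasy** is s² = Σ(xᵢ − x̄ᵢ)²/(n − 1) with the sum over the
*full* R × R matrix and n = R², following the source's literal
convention (the diagonal contributes zero); all other families use
the upper triangle.

**Graph measures.** The documented processing order min–max normalizes
each region's series to [−1, 1] before correlating; since that map is
a positive affine transform per region, the correlation matrix is
unchanged, and the measures are computed on the (raw) correlation
matrix. Negative weights are zeroed and the diagonal removed — the
referenced toolbox routines assume non-negative weights and the source
does not say how negatives were handled. Modularity maximization runs
seeded Louvain restarts (default 10) plus the greedy agglomerative
candidate, each polished by a single-node-move hill climb with
incremental modularity gains; the best Q and its partition are
returned, deterministically for a fixed seed. Global efficiency
interprets "inverted" weights as the reciprocal weight→length map (the
standard convention of the cited routine, not 1 − w), takes all-pairs
shortest paths, and averages reciprocal path lengths over ordered
pairs with unreachable pairs contributing zero.

## Group statistics

Each feature is regressed by OLS on intercept + group indicator
(autism = 1, so beta is autism-minus-control in feature units) +
covariates; site enters as fixed-effect indicator contrasts, sex as a
male indicator. p values are two-sided on the group t. Subjects with
missing feature or covariate values are dropped per feature (features
sharing a missingness pattern are solved in one vectorized pass);
constant features get beta 0, p 1 and a degeneracy flag; rank-deficient
designs (e.g. site confounded with group) are recorded per feature,
not raised. An alternative motion regressor — percent motion-free
volumes instead of mean FD — is available as a covariate switch.
BH-FDR uses the step-up rule (via statsmodels) with missing p values
excluded from the family size; "combined" correction pools all
cohorts' p values into one family, which weakly increases q relative
to per-cohort correction. Feature selection keeps p < .05 strictly and
excludes by rule the families that yield a single scalar per subject
(idiosyncrasy, modularity, global efficiency). Residualization
regresses site/age/sex/motion out of each feature and re-adds the
feature mean.

## Cross-method analyses

Feature–feature and feature–behavior correlations are
pairwise-complete Pearson with per-cell n recorded (behavior
missingness is pervasive in consortium data, so casewise deletion
would be wasteful); the feature graph keeps edges with |r| strictly
greater than 0.4. Method averages are per-subject means over each
family's non-missing features. Leave-one-site-out generalizability
fits the group GLM within one site (necessarily without the site
covariate) and within the pooled remainder (with site indicators) and
correlates the two per-feature t vectors; the design asymmetry is
inherent to the construction. Site factors are mean age, sex ratio,
mean FD, mean retained-volume fraction, the fraction of eyes-open
acquisitions (a proportion, since sites can mix protocols), TR, and
subjects per site; each factor's partial correlation with r_gen
controls for the other six via double residualization, dropping
zero-variance factors from the controlling set with a warning, with p
from the t transform at df = n_sites − 7 − 1 and a marginal-correlation
fallback when sites are too few.

## Synthetic data generator

The generator emulates the *structure* of a multi-site case-control
resting-state study, not its physiology. Each subject's target
correlation matrix is a latent block model (network blocks with
within-block correlation 0.35, between-block levels drawn once per
cohort from N(.05, .07) clipped to [−.12, .25], pair-level
heterogeneity sd .02) plus a per-site intercept (sd .02) and planted
group effects added, on the correlation scale, to targeted pair sets —
homotopic pairs, thalamic/striatal seed maps, within-network pairs, or
all pairs ("global"). The edited matrix is projected to the nearest
positive-definite correlation matrix (eigenvalue floor 1e−3, unit
rescaling), so planting happens through the model rather than post-hoc
matrix edits. ROI series follow X_t = φX_{t−1} + √(1−φ²)·L·ε_t with
Cholesky factor L, giving exactly the target stationary covariance
with first-order autocorrelation φ (default 0.4; lagged features need
non-white signals, and the source used real data with no generative
model to copy). The "lag" effect shifts φ by group, keeping it
independent of the correlation-level families.

Default conditions: 4 sites; per-site group n drawn in [10, 120];
TR ∈ {1.5, 2.0, 2.5, 3.0} s; series length in [120, 240]; eyes-open
probability 0.7 per site. The effect map plants deficits of −0.08
(homotopic), −0.05 (thalamocortical, corticostriatal, within-DMN),
−0.04 (salience set), −0.02 (global) and −0.05 on φ (lag); autism
subjects scale these by 1 + 0.3·z with a standard-normal latent
severity z, which also drives behavior scores. Head motion is FD ~
Exponential(subject mean), with subject means drawn from N(.11, .05)
for autism and N(.10, .05) for controls; under the 0.3 mm rule this
yields roughly 14–19 % censored volumes and a group gap, without any
tuning of the censoring stage. Behaviors (IQ scales negatively;
ADOS/ADI/SRS positively; ADOS/ADI observed only in the autism group)
equal coupling·z plus independent noise on realistic score scales,
with configurable missingness (default 0.3).

The synthetic atlas samples left-hemisphere centroids with minimum
separation 6.2 mm inside boxes sized so all pairwise distances fall in
(5, ~164] mm; right centroids are mirrors plus ≤0.4 mm jitter, so
mutual-nearest pairing provably recovers the planted pairs and the 11
unpaired right-cortical extras are excluded. Deterministic far-corner
anchors plus a bounded resampling loop guarantee every 5-mm distance
stratum above 5 mm is occupied for full-size atlases (hence 32
retained Euclidean bins). Synthetic path lengths cover structurally
connected pairs (connection probability exp(−d/120)) with length
1.1·d + Exponential(100) mm, so path length always dominates
straight-line distance and all ten 50-mm strata are populated. The
reference profile averages connectivity matrices of a simulated
normative cohort with zero planted effects.

What the generator does **not** emulate: hemodynamic response shapes,
physiological noise spectra, scanner artifacts, spatial smoothness,
non-stationarity, or realistic network topography. Passing tests
therefore demonstrate that the *pipeline* recovers what it is supposed
to recover under controlled conditions — not that any particular
clinical finding is true.

## Evaluation studies and problem sizes

`fcmethods.evaluation` backs both the test suite and
`scripts/acceptance.py`; sizes were chosen so each study estimates its
quantity stably:

- **Structural constants** — full 361-region scheme, 10 reference
  subjects.
- **Null calibration** — the region-pair GLM's p < .05 fraction,
  averaged over 10 independent null cohorts (2 sites × 40/group, 361
  regions, ~65 k pairs each). Pair statistics within one cohort are
  positively dependent (shared latent factors, subject-level sampling
  noise common to all pairs), so a single cohort's fraction scatters
  several times more than the binomial standard error; averaging over
  cohorts gives a stable estimate of the type-I rate, which is
  compared to .05 at binomial precision.
- **Pipeline FDR behavior** — 20 full-pipeline runs on small null
  cohorts (2 × 15/group, 45 regions), counting runs with zero q < .05
  discoveries.
- **Recovery** — an isolated homotopic deficit of −0.08 (≈ d 0.8
  against the ~0.10 between-subject sd of a pair correlation) at
  n = 100/group, 60 regions; and the behavior coupling (default 0.3)
  re-estimated against the planted severity at n = 400.
- **Generalizability** — 20 replicates of a 5-site cohort in which
  *only* per-site n varies (10/15/25/40/60 per group; TR, length, eye
  status identical), asking whether subjects-per-site has the largest
  positive partial correlation with r_gen.

## Known limitations

- Site effects are modeled (and simulated) as additive intercepts;
  no mixed-effects or harmonization models are provided.
- The modularity maximizer is a heuristic; the hill-climb polish makes
  it exact on the small graphs we can verify exhaustively, but global
  optimality on 361-node graphs is not guaranteed (nor is it for the
  toolbox routine the procedure mirrors).
- Lagged features require a contiguous run long enough for the lag
  window; high-motion subjects can have missing lag features.
- The interior strength strata of a synthetic reference can be empty
  (block models cluster values more than real cohorts); the drop rule
  handles this, but bin indices are then not contiguous.
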