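# Methods

## Model and procedure

The analysis treats eleven triple-network regions (4 DMN, 4 CEN, 3 SN)
as nodes of one weighted graph per subject. Node signals are mean BOLD
series over 3 mm spheres centred at fixed MNI coordinates. The edge
weight between nodes *i* and *j* is

η_ij = exp(−ξ·d_ij) with d_ij = (1 − c_ij)/(1 + c_ij),

where c_ij is the Pearson correlation of the two preprocessed series
and ξ > 0 (default 2) controls how fast connectivity decays with
correlation distance. d is the Golay correlation-to-distance transform:
nonnegative, zero at c = 1, strictly decreasing in c. η is therefore a
strictly increasing bijection of c ∈ (−1, 1] onto (0, 1].

Degrees are weighted sums over η with self-edges excluded:
Γᵢ = Σ₍ⱼ≠ᵢ₎ η_ij over the single combined 11-node graph;
Γ̄ᵢ = Γᵢ/ΣⱼΓⱼ (sums to 1 per subject); Γ_MN = Σ_{i∈M} Σ_{j∈N} η_ij
over all cross-pairs of two disjoint networks.

The group comparison has three stages, each a two-sided two-sample
t-test: Γ̄ per node; η per edge incident to any node significant in
stage 1; Γ_MN per network pair. Defaults are pooled (Student) variance,
α = 0.05, no multiple-testing correction — matching how such analyses
were typically run; Welch and Benjamini–Hochberg are available by flag.
The pooled default reflects equal group sizes; with n = 16 per group
pooled and Welch are nearly identical anyway.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| ξ (`xi`) | 2 | decay constant of the edge weight; larger ξ compresses weak correlations toward 0 |
| sphere radius | 3 mm | node extraction sphere; membership by voxel-centre distance ≤ radius in mm space (closed ball) |
| discard | 10 volumes | scanner-equilibration prefix dropped before any processing |
| band | 0.01–0.08 Hz | ideal frequency-domain band-pass, DC removed, band edges inclusive |
| TR | 2 s | sampling interval; a conflicting NIfTI header TR is logged and overridden |
| α | 0.05 | per-test significance level, uncorrected by default |

## Preprocessing order and filter dialect

Extraction happens before detrending/filtering. Both temporal steps are
linear maps, so filtering the sphere mean equals averaging filtered
voxels (asserted by test to 1e-8); extracting first is orders of
magnitude cheaper. The band-pass is an ideal DFT-domain projection —
coefficients inside [low, high] kept, all others including DC zeroed —
not a Butterworth or FIR design; it is idempotent by construction.
Amplitude statements about off-grid sinusoids are evaluated via
√2·RMS, since truncating the spectral leakage of an off-grid tone
produces small ringing in the maximum.

Sphere masks depend only on geometry (affine + shape), never on the
data. With thick slices (e.g. 3.5 mm) a 3 mm sphere can contain no
voxel centre; the package raises an error naming the node rather than
returning an empty mask, because whether to resample is a decision the
user must make. Inputs are assumed already in MNI space; slice timing,
realignment, spatial normalisation and smoothing are out of scope.

## The synthetic generator

`SimulationConfig` defines the emulated study conditions: 16 subjects
per group, 230 retained time points, TR = 2 s. Per-group target
correlation matrices are block-structured — `within_network_r = 0.5`
inside each network, `between_network_r = 0.1` across — and the
affected group adds `rai_effect = 0.25` to every rAI-incident cell and
subtracts `dmn_cen_effect = 0.3` on every DMN×CEN cell. These four
values were chosen so both effects are reliably detectable at 16
subjects per group without being trivial at smaller effect grids.
Targets are clipped to (−0.999, 0.999) and repaired to positive
definite by eigenvalue clipping at 1e-6 followed by re-normalisation to
unit diagonal, iterated to convergence — the simplest reproducible
repair; the maximum elementwise change is recorded on the
`CorrelationTarget` (≈ 0.023 for the default affected matrix).

Each subject is generated as: independent unit-variance Gaussian
innovations per node → unit-stationary-variance AR(1) recursion with
coefficient `ar_phi` (default 0.3, a moderate serial correlation
plausible for band-limited BOLD) → mixing across nodes by the Cholesky
factor of the group target → additive white noise of scale `noise_sd`
(default 0.2 relative to unit signal variance, i.e. mild measurement
noise). Because the temporal structure is applied before spatial
mixing and every node shares the same AR coefficient, the expected
inter-node correlation equals the target exactly at `noise_sd = 0`,
for any `ar_phi`; noise attenuates all correlations uniformly. All
randomness derives from spawned `SeedSequence` children of one seed,
so cohorts are bit-reproducible.

What the generator does **not** emulate: hemodynamic-response
convolution, head motion, physiological noise, scanner drift or
spatially correlated noise. Passing tests therefore demonstrate that
the pipeline recovers effects of the assumed statistical form at the
stated sample size — not that such effects are identifiable in real
scans with realistic artefacts.

The volume renderer paints each node's series verbatim into every
voxel of its sphere on a synthetic 2 mm grid and fills the background
with seeded Gaussian noise. Overlapping spheres raise an error (the
default atlas never overlaps at 3 mm radius); the alternative
last-writer-wins rule would silently couple nodes.

## Calibration studies

`triplenet.experiments` reruns the full simulate → connectivity →
comparison pipeline over independently seeded replicate cohorts.
Under the null generator (both planted effects zero) the pooled
rejection rate of each stage is compared to the binomial 95% interval
around α computed at n = 200 replicates (0.05 ± 1.96·√(0.05·0.95/200)
≈ [0.020, 0.080]). The interval is evaluated at the replicate count
rather than at replicates × tests because test statistics within one
replicate share subjects and edges and are therefore positively
correlated; a pooled-count binomial interval would be anti-conservative.
Measured rates sit near 0.05 for all three stages. With the default
planted effects, the rAI degree increase and the DMN–CEN decrease are
each detected with the correct sign in essentially 100% of 100
replicates, and all ten rAI-incident edges show higher mean η in the
affected group — significance of individual edges is not required,
only direction, since single-edge effects are much weaker than their
degree aggregate.

## Numerical choices

- Pearson matrices from `np.corrcoef` are explicitly symmetrised
  ((C + Cᵀ)/2) and clipped to [−1, 1]; BLAS summation order otherwise
  breaks η_ij = η_ji in the last ulp.
- c = −1 maps to d = +∞ and η = 0 (continuous limit) instead of
  raising; this keeps η total and bounded on degenerate input.
- Self-edges are excluded from every sum; a literal j = 1…n row sum
  would add a constant 1 to each Γᵢ.
- Both groups having zero variance in a t-test is resolved by
  convention: equal means → (t = 0, p = 1), unequal → (±∞, 0).
- Algebraic identities are tested at 1e-12 (1e-10 for the Γ̄ sum);
  Monte-Carlo quantities at tolerances stated per test.
- Reports are TSV with 6 significant digits, so fixed-seed runs are
  byte-identical.

## Problem sizes

Unit tests run reduced cohorts (4–6 subjects per group, 80–120 time
points); the acceptance suite and `scripts/acceptance.py` use the full
study scale (16 per group, 230 time points) with 200 null and 100
effect replicates, and a 3-subject volume round trip on the full 11-node
2 mm grid — sizes at which every Monte-Carlo check is stable across
seeds while the whole suite stays fast on one CPU.

## Known limitations

- The inter-network degree is implemented literally as the positive
  sum Ση over cross-pairs, so per-subject values are strictly positive;
  published tables of this quantity that imply negative subject values
  must involve an additional, undocumented baseline subtraction and are
  not directly comparable.
- No covariate adjustment, permutation inference, thresholded graph
  metrics (clustering, path length, modularity) or plotting; reports
  are tabular.
- The simulator's group effect acts on correlations homogeneously
  across subjects; between-subject effect heterogeneity is not modelled.
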