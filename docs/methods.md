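# Methods

## Segmentation chain

The per-frame chain is: channel-mean grayscale → 256-bin histogram → metric
threshold → binarize → 8-connected particle labeling → hole filling →
relabeling → size filter → pixel-count area. Every frame is thresholded
independently, matching an online acquire–process–record loop; no state is
carried between frames.

**Grayscale.** `round((R+G+B)/3)` with round-half-up, so the conversion is
bit-reproducible across platforms. (For a three-channel mean the fractional
part is always 0, 1/3 or 2/3, so the half-up rule never actually fires; it is
fixed anyway to pin the contract.)

**Metric threshold.** The threshold is the gray level `k` minimizing
`Σ_{i≤k} h(i)|i−μ₁| + Σ_{i>k} h(i)|i−μ₂|`, with μ₁ and μ₂ the count-weighted
mean levels of the low and high class. Only splits leaving both classes
nonempty are candidates — μ₂ is undefined otherwise — and a histogram with
all mass at one level raises a degenerate-histogram error that callers treat
as "frame unsegmentable". Ties break to the smallest `k`. Because the cost is
exactly flat across stretches of empty bins, floating-point summation order
can perturb it by ~1e−12 and flip the argmin; minimizers are therefore
compared with a relative tolerance of 1e−9 before the smallest-k rule is
applied, in both the implementation and the brute-force oracle.

**Connectivity.** Foreground particles use 8-connectivity and background
holes 4-connectivity — the standard complementary pairing, so a diagonal
foreground chain still encloses a hole. Hole filling (backed by
`scipy.ndimage.binary_fill_holes`) fills every background component not
4-connected to the image border; it never removes foreground and is
idempotent. Labeling is backed by `scipy.ndimage.label`. Both are checked
against hand-written flood-fill oracles in the tests.

**Size filter.** Particles with fewer than `min_pixels` pixels are dropped.
The default is 200 px: dust specks on the cloth are tens of pixels at most
while the smallest sample of interest stays in the thousands, so the default
sits two orders of magnitude below the signal with a wide safety margin on
both sides. It is plain configuration, not an inferred constant.

**Degenerate frames.** A frame where no particle survives filtering, or that
cannot be thresholded, is recorded as a *missing* area, not zero, and is
excluded from modeling. An unsegmentable first frame aborts the run, since
A₀ normalizes everything downstream.

## Moisture bookkeeping

`MC = (m_t − m_d)/m_d` (dry basis, g/g), `MR = MC_t/MC_0`, `AR = A_t/A_0`;
wet-basis fractions convert by `w/(1−w)`. Frames and weight samples are
aligned by nearest time within half the median frame interval — both streams
are logged every 0.5 min in the intended setup, but their clocks need not
coincide sample-for-sample. Unmatched frames keep their AR and carry missing
MR. Scale noise near the endpoint can push `m_t` marginally below `m_d`; by
default the builder clips MC at zero with a warning (strict mode raises
instead). Replicate runs on identical time grids can be averaged
arithmetically per time point.

## Regression models

Both regressors map AR → MR. The series are already on a [0, 1] scale by
construction, so no further normalization is applied.

**ELM.** Input-to-hidden weights and biases are drawn once from
uniform(−1, 1) (seeded) and frozen; the hidden output is
`H = sigmoid(X·W + b)`; the output weights solve `min‖Hβ − T‖` via the SVD
pseudoinverse with the standard `max(n, L)·eps` relative singular-value
cutoff, giving the minimum-norm solution when H is numerically
rank-deficient. Default hidden size 12. Note that with a one-dimensional
input the sigmoid features are strongly collinear, so H's condition number
grows quickly with L; past numerical rank the cutoff truncates and the
training error may tick up by O(1e−5) instead of decreasing — visible in the
nested-basis monotonicity test's tolerance.

**ANN.** One tanh hidden layer (default 10 nodes), linear output, trained by
Levenberg–Marquardt on `Σr² + λ‖w‖²` with an analytic Jacobian. Damping
starts at μ = 1e−3, ×10 on a rejected step and ÷10 on acceptance; failure to
find a descent step after damping escalation is treated as convergence on
the regularized objective (a singular system that never solves raises).
Weight decay defaults to λ = 1e−4. Early stopping watches a seeded 20 %
validation split with patience 6 (max 1000 epochs) and restores the
best-validation weights. Training is bitwise deterministic in the seed.

**Metrics.** RMSE, MAE, R². Zero variance in the measured values makes R²
undefined; it is reported as NaN with a warning rather than ±inf.

**Protocol.** `train_predict_protocol` fits on one run's (AR, MR) pairs and
evaluates on both that run and a second, independent run — the
train-on-one-experiment, verify-on-another design.

## Synthetic generator

The generator renders what the rig would see: bright disks (gray ≈ 200) on a
dark cloth (≈ 30) with Gaussian gray jitter (σ = 6), fixed bright dust
specks (radius 1–2.5 px, well under the size filter), and transient dark
bubbles (gray ≈ 45, radius 3–8 px, Poisson arrivals at 0.3 events per disk
per frame, 2–6 frame lifetimes) kept strictly interior to the disks with a
2 px rim so they are always completely encircled holes. Disk radii follow
`r_t = r₀·√AR_t`. The scene-noise and bubble random streams are separated,
so the same seed with bubbles disabled renders the identical scene minus the
bubbles — which is what makes the "bubbles change the final area by exactly
0 pixels" invariant testable as an exact equality.

The default drying law is Page-type, `MR(t) = exp(−k·tⁿ)` with k = 0.068,
n = 1.2: a standard monotone drying curve that reaches the 15 %-wet-basis
stopping ratio (MR ≈ 0.0178) at t ≈ 30 min, giving 61 frames on the 0.5-min
acquisition grid. Shrinkage couples to moisture through the simplest
monotone link, `AR = 1 − c·(1 − MR)` with c = 0.6 (final area ratio ≈ 0.41,
in the range typical of fruit-slice drying); the modeling layer does not
assume this link — the regressors are nonlinear. Masses invert the
bookkeeping, `m_t = m_d·(1 + MC₀·MR(t)) + ε`, with m_d = 6 g and
MC₀ = 9.87 g/g (initial mass ≈ 65.2 g, a tray of fresh high-moisture fruit)
and scale noise σ_mass = 0.5 % of the initial mass (≈ 0.33 g), i.e. a
moisture-ratio noise floor σ_MR = σ_mass/(m_d·MC₀) ≈ 0.0055. Default frames
are 400×400 px with two disks (r₀ = 70 and 55 px).

**What the generator does not emulate:** non-circular and irregularly
deforming samples, uneven illumination and shadows, specular glints outside
bubbles, camera vignetting or focus drift, sample translation during drying,
and case-hardening-style departures from a single smooth MR(t) law. Passing
tests therefore demonstrate the correctness of the computation and its
noise-floor behaviour under the stated imaging model, not robustness to
every real-rig artifact.

## Problem sizes and numerical choices

The test suite and acceptance script use 1,000 random histograms for the
threshold oracle, 500 random 64×64 masks for the hole-fill oracle, 50 random
one-frame scenes (disk radii 20–60 px) for area fidelity, 200 random
instances for the ELM solver oracle, and 20 seeded experiment pairs at the
full 61-frame default for the end-to-end recovery study — together about two
minutes on one CPU, chosen so the whole suite stays quick while every oracle
runs at a scale where disagreement would be visible.

On those 20 pairs the ELM test R² exceeds 0.999 on every pair and the median
test RMSE is ≈ 1.15× the injected noise floor. The ELM and ANN are
statistically indistinguishable here: both reach the noise floor on a smooth
one-dimensional law, their paired test-RMSE differences are ±0.0005 with
mean ≈ 0, and the per-pair winner is effectively a coin flip. A per-seed
majority ranking between them is therefore not a stable property of these
conditions (the corresponding acceptance test documents this by failing),
even though on real data an ELM's insensitivity to training hyperparameters
can give it a practical edge over an LM-trained network.

## Known limitations

- The metric-threshold cost is minimized exhaustively over all 255 candidate
  splits per frame; this is O(N²) in the number of gray levels but trivially
  fast at N = 256.
- The area measure counts pixels; it is unbiased for rasterized disks
  (within 0.3 % of πr² at r ≥ 20 px) but carries no sub-pixel boundary
  refinement.
- `build_run` loads frames eagerly when given arrays and streams file paths
  one at a time; memory use with in-memory sequences is the caller's choice.
- The ANN trains full-batch; it targets the small-sample regime (tens to
  hundreds of points per run), not large datasets.
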