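# Methods

## Models

### Colonization bottleneck

Seeding is a per-cell Bernoulli trial with survival probability q, identical
for all barcodes (the library is isogenic apart from the tag). A barcode
contributing n_i = round(N·f_i) cells to an inoculum of N cells founds the
tumor with Binom(n_i, q) cells; rounding resolves fractional expected counts
before the draw. Everything downstream follows from the binomial:
observation probability 1−(1−q)^{N·f}, expected observed barcodes
B̄(q) = Σ 1−(1−q)^{N·f_i}, and the founder-size percentages (77/20/2.6% for
0/1/2 cells at N·f = 100, q = 2.6×10⁻³). q is recovered from an observed
barcode count by bisection on B̄(q), which is strictly increasing with
B̄(0)=0; bisection (200 iterations, relative tolerance 1e-8 on the bracket)
is used instead of a generic root-finder because the bracket is guaranteed.
The attainable range is checked first and violated bounds are reported in
the error. Note the inferred q absorbs *all* early losses, including
stochastic extinctions during the first hours of growth, and is therefore a
slight underestimate of pure seeding survival; no correction is applied.

### Consumer–resource dynamics

B clones share one resource s. Per-capita growth is Monod g·s/(s+k)
(well-mixed niche) or Contois g·s/(s+k·N_i) (local growth limitation: each
clone saturates its own niche in proportion to its size). Growth consumes
resource with inverse yield γ; replenishment from surrounding tissue is
D(s₀−s). Environmental stochasticity enters as multiplicative noise σ·η_i·N_i
with independent unit white noises; the in-vitro variant replaces it with
demographic noise η_i·√(μ·N_i) (square-root argument clamped at 0).

Only s₀/γ and k/γ affect cell counts, so the integrator works in
resource-per-γ units internally; trajectories are bit-identical under
(s₀, k, γ) → (c·s₀, c·k, c·γ), and the test suite asserts exact equality.

Default parameters (the intratumor condition): g = 2 hr⁻¹, σ = √g,
D = 1 s⁻¹ = 3600 hr⁻¹, s₀/γ = 5×10⁴, k/γ = 1. The intravenous condition
uses k/γ = 0.01 (fewer survivors, larger per-clone niche). These values tie
the saturation load N ≈ B·s₀/k and the observed barcode counts together;
the package treats them as defaults on `SimulationParams`, all overridable.

### Stationary law

When k·N_i ≫ s the Contois model linearizes to dN/dt = c + σηN with
c = gDs₀/(Dk+Bgγ) after eliminating the resource at steady state. The
Fokker–Planck stationary solution (Itô convention) is
p(n) = (n*/n²)e^{−n*/n}, n* = 2c/σ², with CCDF c(n) = 1−e^{−n*/n} and
rank-frequency curve f(r) = −n*/(N·ln(1−r/B)). For r ≪ B this is Zipf's law
f ≈ n*B/(N·r). `dynamics.simulate_reduced` integrates the reduced Langevin
directly and is checked against the closed forms by a KS test.

## Numerical scheme

* **Euler–Maruyama, Itô.** Per-clone noise increments are independent
  N(0, dt). Itô matches the diffusion term σ²n²/2 used in the stationary
  derivation. An optional geometric (exact log-normal) update for the
  linear part exists behind a flag; the default is the plain Euler scheme
  for fidelity to the derivation.
* **Step size.** The abundance step is dt ≤ 10⁻³ hr (σ√dt ≈ 0.045 at the
  default σ); larger steps raise an error unless explicitly overridden.
* **Stiff resource.** With D = 3600 hr⁻¹ the resource relaxes ~10³× faster
  than the cells, so by default it is advanced by its quasi-steady state:
  the unique root of D(s₀−s) = consumption(s) on [0, s₀] (the balance is
  strictly decreasing in s). Monod consumption gives a closed-form
  quadratic root; Contois uses warm-started Newton iterations safeguarded
  by bisection, converged to 1e-12 relative. Explicit sub-stepping with
  dt_s ≤ 1/(2D) is available as `resource_policy="substep"` and is the
  right choice for batch-like settings (small D), where the quasi-steady
  state is not a valid approximation.
* **Zero boundary.** Multiplicative-noise Euler steps can cross zero;
  crossings clamp to 0, which is absorbing (both noise and growth vanish).
  With the extinction threshold enabled, clones dropping below it
  (default 1 cell, the continuum model's resolution) are removed
  permanently; it is disabled by default because extinctions only matter
  immediately post-bottleneck, when clones are small.
* **Failure handling.** Non-finite states abort with a diagnostic rather
  than propagate NaNs.
* **Generations axis.** Elapsed time is converted to generations as
  g·t/ln 2, i.e. doublings at the maximal growth rate.

## Synthetic data

The generator emulates the experiment's statistical structure:

* **Inoculum.** Log-normal frequencies with σ_ln = ln(F)/(2·z_{(1+m)/2}) so
  the central mass m spans a fold-range F (defaults m = 0.99, F = 6). After
  drawing, log-deviations are rescaled so the *empirical* central-mass
  quantile ratio equals F exactly — the spread is a calibrated property of
  the library rather than a fluctuating one. Barcodes are unique random
  20-mers over ACGT.
* **Sequencing.** Each technical replicate is an independent multinomial
  draw of `depth` reads from the clone frequencies; depth defaults to 10⁶
  reads (RPM-natural). Real amplicon sequencing adds PCR bias, chimeras
  and index hopping — none are modeled, so passing tests validate the
  sampling statistics, not protocol artifacts.
* **Reads.** Optional FASTQ rendering: 0–3 random pad bases, the
  `ACCAA[20nt]TGTAG` anchor structure, i.i.d. substitution errors,
  constant Phred qualities (Q30 unless configured). The matching
  extractor requires exact anchors (a simplified stand-in for read
  clustering), with an optional greedy Hamming-≤2 merge into the more
  abundant neighbor.
* **Experiments.** Per tumor: binomial bottleneck → SDE integration →
  multinomial sequencing at each sampled day; ground truth (q, parameters,
  founder counts) rides along in the bundle manifest. All randomness
  derives from one integer seed via named streams (crc32 of stream names
  → SeedSequence spawn keys), so adding a stage never perturbs another
  stage's draws and bundles are bit-reproducible.

## Statistics

Rank-frequency tables drop zeros, sort descending with ties broken by
barcode id, and renormalize. Power-law fits f = βr^(−α) come in two
flavors: nonlinear least squares on the untransformed pairs (the study's
convention; head-weighted) and OLS of log₁₀f on log₁₀r (the Zipf-plot
slope). The default fit range is the full detected range. For *reading
off the Zipf exponent* the workflows restrict the OLS fit to ranks
1..max(100, B/10): in that window the model's own rank-frequency curve is
a pure power law to within ~5%, while at r → B the −ln(1−r/B) term bends
the curve down regardless of whether the data follow the law — the
full-range OLS slope of the exact law itself is −1.26. The window always
spans at least two decades at the problem sizes used.

Shannon entropy uses natural log by default (base configurable). The
master-list filter keeps barcodes strictly above 10 RPM in ≥2 of 4 T0
replicates ("above" read as strict; both thresholds configurable).
Fisher's exact test (two-sided, minimum-likelihood convention) and
Spearman correlation come from scipy; Bonferroni is min(1, m·p).
Lineage arithmetic: doublings = log₂(final size), generation time =
60·hours/doublings, mutation-free probability = (1−μ)^doublings.

## Problem sizes and defaults chosen here

* The in-silico intratumor scenario uses a 10,000-barcode inoculum at the
  study's mean of 125 cells per barcode (N = 1.25×10⁶), giving ≈2.7×10³
  single-cell founders after the q = 2.6×10⁻³ bottleneck — a quarter-scale
  version of the experiment that preserves every per-barcode rate. The
  reported day-1 Zipf slope is the median over 3 simulated tumors,
  mirroring how the exponent is summarized across tumors.
* Parameter-recovery exercises run at the full study scale (40,000
  barcodes, N = 5×10⁶), which is cheap because no dynamics are involved.
* The Monod/Contois contrast integrates 1,500 clones initialized at 100
  cells (the no-bottleneck regime, where the contrast is about the growth
  law, not the initial condition) for 500 generations with the extinction
  threshold enabled.
* The reduced-Langevin ensemble uses 2×10⁴ trajectories, 40 hr at
  dt = 10⁻³ hr, started at n*; the KS comparison is restricted to the
  central 90% of the analytic mass.

## Limitations

* No spatial structure: the Contois term is a mean-field surrogate for
  local crowding, not a PDE tumor model.
* No immune compartment, inter-tumor migration, PCR/chimera artifacts, or
  host-read contamination.
* The continuum SDE under-resolves clones of a few cells; the demographic
  mode approximates birth–death noise but is not an exact Gillespie
  process.
* Inferred q conflates seeding survival with immediate post-seeding
  extinction (an acknowledged underestimate; no correction implemented).
* Synthetic libraries have exactly calibrated spread and independent
  multinomial replicates; real T0 replicates share extraction noise, so
  real master lists are noisier than synthetic ones.
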