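# Methods

## Scope

`jetpbm` models the micronization of pharmaceutical powders in a spiral jet
mill and the statistics used to connect milling outcomes to material
properties and process settings. The package covers four linked layers:

1. a discretized population balance model (PBM) of the mill chamber;
2. extraction of in-die mechanical and energy properties from compaction
   traces (Rippie–Danielson analysis);
3. staged calibration of the PBM against measured particle size
   distributions (PSDs) with an identifiability check;
4. design-of-experiments (DoE) regression and latent-variable analysis
   (MLR, PCA, PLS with VIP scores).

A synthetic-data layer generates every input with known ground truth so each
estimator can be validated by recovery.

## The mill model

The chamber is treated as a single well-mixed hold-up on a geometric size
grid (default 80 classes, 0.1–500 μm; class 1 smallest). The state is the
mass per class M_i (kg). For fixed parameters the balance is linear:

    dM_i/dt = Ṁ_in,i − c(x_i) M_i − S(x_i) M_i + Σ_{j>i} b_{i,j} S(x_j) M_j

* **Feed.** Ṁ_in,i is the unmilled volume fraction times the solids feed
  rate ṁ_s. Number-based feed rates follow by dividing by ρ·v(x_i), with
  v(x) = (π/6)x³ the sphere volume; throughout, x is a sphere *diameter*,
  consistent with laser-diffraction dv-values.
* **Classification.** The central outlet self-classifies. Its per-mass exit
  rate is a complement cumulative log-normal,
  c(x) = (k/2)(1 − erf((ln x − μ_c)/(√2 σ_c))), falling from k (fines always
  leave) to zero (coarse particles are retained). k is fixed at 1 s⁻¹: the
  steady outlet is invariant under rescaling (k, α) jointly, so only the
  balance of classification and breakage is identifiable; fixing k makes α
  interpretable relative to that choice.
* **Breakage.** Particles below a critical size x_crit do not break
  (fracture requires a minimum stored elastic energy); above it the specific
  rate is S(x) = α (x/x_n)^λ with x_n the largest grid center. Fragment
  masses follow the power-law cumulative distribution B_{i,j} = (x_i/x_j)^γ.
  Differencing B gives per-class fragment fractions; the mass that the
  truncated power law leaves unassigned (1 − B_{j−1,j}) is added to the
  largest daughter class j−1, so each fragment column sums to exactly 1 and
  breakage conserves mass identically. The smallest class has no daughters
  on the grid, so its breakage rate is forced to zero — a discretization
  closure, not a physical statement.

**Steady state** is obtained directly: the system matrix
A = diag(c+S) − bS couples each class only to larger ones, so A·M = Ṁ_in is
one triangular back-substitution (no time stepping, no nonnegativity
issues). A class with zero exit and zero breakage that receives feed has no
steady state; this is reported as a *mass trap* naming the class. The
transient path (stiff BDF with the constant Jacobian −A) exists for
validation; `integrate_to_steady` advances in doubling chunks of the slowest
throughput time 1/min(c+S) until the outlet PSD changes by less than 1e-6
per chunk. The two routes agree to <1e-4 by construction of the tests, and
in practice to near machine precision.

**dv-percentiles** invert the cumulative volume curve with log-linear
interpolation across class edges, matching how laser-diffraction software
reports dv10/dv50/dv90.

## Compaction mechanics

A single load–unload cycle is segmented into rearrangement (force below 1 %
of peak — configurable; the instrument literature gives no canonical
threshold), compaction (up to the force peak), and decompression. The
decompression segment is treated as elastic unloading of the confined
compact and is where both constants are fitted, because the radial-
transmission and constrained-modulus relations hold differentially there:

* ν from the ordinary-least-squares slope m of σ_z against σ_r over the
  whole unloading segment: ν = 1/(1+m). OLS over the full segment (no
  windowing) is the simplest reproducible choice; a window is exposed in
  configuration if an instrument produces nonlinear tails.
* E from the slope s of σ_z against the logarithmic strain
  ε_z = ln(ρ/ρ0), with the in-die density ρ computed from tablet mass, die
  cross-section and punch separation: E = s (1+ν)(1−2ν)/(1−ν).

Axial stress uses the 6 mm punch area; radial stress is the mean of the two
die-wall sensors (already averaged in the input format).

Energy parameters come from trapezoidal areas under the force–displacement
curve: the unloading area is the elastic work W_elastic, the loading area
from onset to peak is the compression work W_compress, and
W_compact = W_compress − W_elastic, so the additivity
W_compress = W_compact + W_elastic is exact by construction. Elastic
recovery ER = 100·W_elastic/W_compress (%); specific work of compaction
SWC = W_compact/m_tablet (J/g).

## Calibration

Seven parameters cannot be estimated jointly from one steady-state PSD, so
identification is staged per experiment:

1. k fixed (see above);
2. (μ_c, σ_c) fitted by least squares of the complement cumulative
   log-normal to the coarse half of the observed cumulative volume PSD
   (classes at or above the dv50) — the classifier acts as a virtual screen
   and shapes exactly that tail;
3. x_crit identified as the milled dv10 (default quantile 0.10): particles
   below it were produced by breakage but no longer broke;
4. (α, γ, λ) estimated against the observed PSD.

The objective is MMDsum: the squared maximum mean discrepancy (biased
V-statistic, Gaussian kernel on log10 size, median-heuristic bandwidth)
between model and observed PSDs, summed over the volume and the number
basis. Using both bases makes the objective sensitive to fines (number
basis) and coarse mass (volume basis) simultaneously.

The optimizer is a seeded global-best particle swarm (30 particles, 200
iterations, inertia 0.72, cognitive = social = 1.49, reflective bounds; α
searched on log10 scale over [1e-4, 1e3] s⁻¹, γ ∈ [0.1, 5], λ ∈ [0, 5]),
followed by a bounded Nelder–Mead polish of the swarm best. The polish
matters: the objective valley is strongly anisotropic because α and λ can
partially compensate over the one-decade size window the data actually
constrain (the power-law pivot x_n lies at the far grid edge), and a swarm
alone stalls on that valley floor; the simplex follows it to the minimum.
Everything is deterministic for a fixed seed.

## Identifiability

`ia_profile` fixes one parameter on a log-spaced grid (default 11 points
over 0.2×–5× the calibrated value) and re-optimizes the remaining free
parameters with a reduced swarm (15 × 80) plus polish, with per-point seeds
derived from the profile seed. `u_shape_verdict` declares a parameter
identifiable iff the profile decreases monotonically to an interior minimum
and increases after it, with 2 % relative slack absorbing optimizer noise; a
profile flat to within the slack, or with its minimum on the boundary, is
non-identifiable. On noise-free synthetic data all three of α, γ, λ are
U-shaped with the minimum at the generating value; profiling k with α free
yields a flat valley at the noise floor — the collinearity that motivates
fixing k.

## DoE statistics

The milling design is a 2² full factorial in gas flow rate (2.2/9.0 m³/h)
and solids feed rate (5/15 g/min) with a centerpoint (5.6, 10). MLR runs on
coded (−1/0/+1) factors so coefficients are directly comparable; terms may
include interactions and quadratics. Goodness of prediction is
Q² = 1 − PRESS/TSS with leave-one-out PRESS via the hat-matrix identity; Q²
for PCA uses row-wise leave-one-out reconstruction error, for PLS row-wise
refitting. Commercial chemometrics suites use proprietary cross-validation
groupings, so Q² values are comparable in kind but not digit-for-digit.
PCA runs on the autoscaled material-property block; PLS (NIPALS, via
scikit-learn behind the module surface) links material properties and
process settings to milling performance or to calibrated PBM parameters.
VIP uses the standard weighted-sum-of-squares formula; the mean squared VIP
is 1 by construction.

## Synthetic data

The generator emulates a material-limited milling campaign:

* **Unmilled PSDs** are split log-normals (separate geometric sd below and
  above the median) so that the asymmetric dv10/dv50/dv90 triplets of real
  grade sets can all be matched; the default library holds eight grades with
  medians 10–105 μm.
* **Compaction traces** are three-phase cycles whose unloading branch
  satisfies both fitting relations exactly for the chosen (E, ν), with the
  loading branch joining the elastic line continuously at the peak, so the
  estimators are exactly invertible at zero noise.
* **Milled PSDs** come from the forward steady-state PBM at parameters set
  by a link rule carrying the studied mechanism directions: ln x_crit and
  the classifier cut decrease linearly in coded gas flow (−0.6 and −0.5
  ln-units per coded unit), ln α increases with Young's modulus (0.35 per
  GPa above 5 GPa), and a weak choking term (+0.1 ln-units per coded feed
  rate) raises the cut at high feed. The directions are the observed
  mechanisms; the magnitudes are package choices exposed in `LinkRule`.
* **Noise** is multiplicative log-normal on per-class volume fractions with
  renormalization, mimicking laser-diffraction replicate scatter; replicate
  centerpoints at 2 % noise keep dv RSDs below 10 %.

What the generator does *not* emulate: bimodal or attrition-fines PSDs
(the simplified fragment law is monomodal by design), lump formation,
tribo-electrification, day-to-day feeder drift, and any mechanistic link
from gas dynamics to the kernels. Passing recovery tests therefore shows
the estimators are correct on data from the model family they assume, not
that the model family captures every real powder.

## Numerical choices and limitations

* Grid: geometric, n = 80 (0.1–500 μm) for simulation; optimization-heavy
  tests and the acceptance script use n = 40, where the forward solve is a
  sub-millisecond triangular solve.
* PSD file rebinning allocates bin volume proportionally in log size and
  conserves total volume exactly; inputs extending beyond the model grid are
  rejected rather than silently truncated.
* Classes with zero throughput and zero feed are regularized (unit diagonal)
  in the steady solve; they carry no mass.
* The α–k product degeneracy is structural; reported α values are relative
  to k = 1 s⁻¹.
* Per-experiment calibration only: no joint multi-experiment estimation with
  shared parameters, no gradient-based or Bayesian alternatives.
* The fragment-law closure concentrates residual parent mass in the largest
  daughter class; for γ ≳ 3 this makes near-parent fragments dominant, which
  is intended (attrition-like chipping) but means γ is only weakly
  constrained once most fragments fall below the classifier cut.
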