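# Methods

## Model

A single enzyme species E converts substrate to product by first-order
kinetics (rate constant k = k_cat/K_M, far below saturation). Space is a
sphere of radius R₀ (the "basin", one of many identical non-overlapping unit
volumes, hence zero flux across its surface by default). Inside sits a
droplet of radius R₂ containing all N_total enzyme copies; a partner-protein
interaction condenses part of the pool into a central cluster of radius R₁.
The clustering excess γ = n₁/n₂ fixes the split n₁ = N·γ/(γ+1) (clustered),
n₂ = N/(γ+1) (dispersed). The dispersed pool permeates the whole droplet
including the cluster region, so the enzyme density is

    n(r) = n₂/v_drop + n₁/v_cluster   on [0, R₁)
           n₂/v_drop                  on [R₁, R₂)
           0                          on [R₂, R₀]

Substrate c₀ and product c₁ obey

    ∂c₀/∂t = D∇²c₀ − k n(r) c₀ − α₀(c₀ − c₀*)
    ∂c₁/∂t = D∇²c₁ + k n(r) c₀ − β c₁

α₀ relaxes the substrate toward a homeostatic level c₀* (replenishment by
the surrounding metabolism or the assay reservoir); β is an effective
first-order product removal (consumption downstream, degradation, or
read-out loss). β > 0 is required for a steady state under a zero-flux outer
boundary, otherwise product would accumulate without bound.

### Exact steady state

At steady state each region has constant linear removal, so each species is
a constant particular solution plus modified-Helmholtz modes
{sinh(κr)/r, cosh(κr)/r} with κ² = (local removal)/D; for a region with zero
linear removal the basis degenerates to {1, 1/r}. The substrate solves
independently; its solution enters the product equation as a source whose
particular response is closed-form — a constant k·n·P/β plus terms
proportional to the substrate modes with coefficients k·n·A/(β − Dκ₀²). The
measure-zero resonant case β = Dκ₀² (within 10⁻⁹ relative) is handled by
perturbing β by 10⁻⁸ relative with a warning rather than implementing the
resonant particular solution. Five matching coefficients per species
(regularity kills one mode at the origin) are found from a 5×5 linear
system: value and flux continuity at R₁ and R₂ plus the outer condition.
Columns are rescaled by their largest entry before solving, which keeps the
system well conditioned even when sinh(κr) spans many orders of magnitude.
Phase averages and conservation integrals use the closed-form shell
integrals of the basis, not quadrature.

Two solver options reflect assay idealizations: an "excess-substrate" mode
clamps c₀ ≡ c₀* (substrate never limiting), and a "clamped" outer boundary
fixes concentrations at R₀ for sensitivity checks.

### Finite-volume oracle

`numeric_oracle` discretizes the same equations with a conservative
finite-volume scheme on a radial grid (default 400 nodes, 3× refinement
within [0.5R₁, 2R₁]; R₁ and R₂ are grid nodes and reaction coefficients are
averaged exactly over each control volume). Discrete flux balances hold to
solver precision, grid convergence is ~O(h²), and steady solutions agree
with the analytic ones to relative L2 ≲ 10⁻³ at default resolution — this
cross-check runs over randomized parameterizations in the test suite.
Transients use backward Euler stepped substrate-first; the scheme is
unconditionally stable in D, so the step size is set by accuracy
(default t_end/400) rather than a CFL-type limit.

## Units and parameters

Internal units: μm, s, μM, enzyme copies. A catalytic efficiency supplied in
μM⁻¹s⁻¹ converts via 1 μM = 602.214 copies/μm³. Bundled presets
(`presets.yaml`):

| parameter | in_vivo | in_vitro | meaning |
|---|---|---|---|
| R₁ (μm) | 0.1 | 0.25 | cluster radius |
| R₂ (μm) | 2.0 | 5.0 | droplet / cytoplasm radius |
| R₀ (μm) | 5.0 | 10.0 | basin radius (package choice) |
| k (μM⁻¹s⁻¹) | 1.0 | 1.0 | catalytic efficiency |
| D (μm²/s) | 5 | 300 | metabolite diffusivity |
| α₀ (s⁻¹) | 0.001 | 5 | substrate replenishment |
| β (s⁻¹) | 0.5 | 0.5 | product removal |
| c₀* (μM) | 100 | 100 | homeostatic substrate |
| N_total | 10⁶ | 6×10⁴ | enzyme copies per droplet |

The in-vivo radii are the published geometry of the cellular model; the
in-vitro droplet radius is half the ~10 μm mean assay droplet diameter. The
in-vivo kinetic values were calibrated once, within physiologically
defensible ranges, against the published prediction that cluster product
accumulation commences near γ = 5 and plateaus toward γ = 50, then frozen
(see "Onset and plateau" below). The calibrated regime is strongly
substrate-depleted (slow α₀ against a large clustered sink), which is what
delays the onset; it is not the substrate-excess idealization.

## Onset and plateau of the γ response

`find_onset_and_plateau` uses an explicit operational definition: onset
(plateau) is the smallest γ at which a monotone sweep response exceeds the
baseline by 5% (95%) of the baseline-to-asymptote rise, located by linear
interpolation between sweep points. The thresholds are parameters because no
standard definition exists.

A structural property of this model family is worth recording: whenever the
response is linear in (n₁, n₂) — exactly true in the excess-substrate mode,
approximately true whenever depletion is mild — the rise fraction collapses
to γ/(γ+1) regardless of every other parameter, putting the 5% crossing at
γ ≈ 0.053 and the 95% crossing at γ ≈ 19, a fixed ~360× span. Substrate
depletion can delay the onset (clustering initially trades local gain
against local substrate exhaustion) but stretches rather than compresses the
span: across a broad randomized search of (α₀, β, N, D, R₀), both boundary
modes and both response definitions, the 5%→95% span never fell below ~19×.
An onset of 5 together with a plateau of 50 (a 10× span) is therefore not
attainable under this 5%/95% definition; the calibrated in-vivo preset
yields onset ≈ 3 and plateau ≈ 93 on a γ ∈ [0, 100] sweep, with ~59% of the
rise reached at γ = 50. The corresponding acceptance test records this
honestly and fails on the plateau bound. The droplet/bulk partition ratio
is monotone non-decreasing in γ and sigmoid on a log-γ axis, as asserted in
the suite.

## Assay analysis conventions

* **Velocity**: slope of *total* product (droplet + supernatant) against
  time over the first three time points (initial-rate convention; the
  window is a parameter), divided by enzyme amount; reported in s⁻¹.
  Velocity is invariant to how product splits between phases.
* **Percent enhancement**: 100·(v − v₀)/v₀ by default, so 1.1× baseline
  reads 10% and 2.8× reads 180%; a percent-of-activity convention
  (100·v/v₀) is available by flag. Standard errors propagate the shared
  baseline estimate (delta method) — without that term, per-condition SEs
  understate the coherent error all conditions inherit from v₀.
* **Partition ratio**: (droplet amount/droplet aliquot volume) /
  (supernatant amount/supernatant aliquot volume); equal 10 μL aliquots by
  default.
* **Ratio → γ map**: the model does not predict how partner abundance sets
  cluster occupancy, so the map is empirical: monotone piecewise-linear in
  log10(1+ratio) through anchors, with ratio 0 → γ 0 always. Default
  anchoring scales normalized enhancement to a configurable γ_max = 50;
  explicit anchors override it. It preserves ordering; it is not
  mechanistic.

## Tracer conventions

MDV = isotopologue abundances normalized to sum 1;
FC = Σᵢ i·s(i)/n ∈ [0, 1]. No natural-isotope-abundance correction is
applied (a no-op hook marks the insertion point): the analyses compare
labeling *dynamics* between strains measured identically, where the
correction cancels to first order; absolute flux values would need it.
Collection labels T0…T5 map to {pre-dilution, 3, 4, 5, 6, 7} h. Metabolic
steady state is detected as the largest trailing window (≥ 3 points) in
which no metabolite shows a significant intensity trend (two-sided
regression-slope test, α = 0.05) and interval uptake rates stay within 20%
relative spread — both thresholds configurable, since no standard values
exist. Glucose uptake comes from regressing ΔS on ΔC through the origin
(slope −q/m).

## Metabolomics conventions

Intensities are divided by the sample's OD. Fold changes are stored as
log_base(strain mean/control mean); the negated rendering used in heat maps
is presentation only. Branchpoint ratios are ratios of strain means
normalized so the control equals 1; hypothesis tests compare replicate-wise
numerator/denominator ratios between strain and control (a documented
choice — testing raw intensities is also defensible but conflates level and
ratio effects). The Mann–Whitney test is exact for group sizes ≤ 8: the
two-tailed p doubles the smaller tail of the full C(n₁+n₂, n₁) permutation
distribution of the average-rank U statistic and caps at 1, which handles
ties exactly and reproduces p = 2/70 ≈ 0.029 for complete separation at
4 vs 4. Larger groups fall back to the tie-corrected normal approximation,
tagged as such. No multiple-testing correction is applied by default.

## Synthetic data

Generators emulate the three experiment families at the study's design
points (assay: ratios {1,10,50,100,250,500}:1, 3 replicates, times
{0,10,20,30,40,60} min; tracer: 4 metabolites × 3 strains × 3 replicates,
55% labeled-glucose feed; metabolomics: 7 strains × 4 replicates × 22
metabolites). Truth values are anchored to the printed experimental
outcomes (10% → 180% enhancement ladder, 2-fold partitioning at 40 min,
3.5× 2-oxoglutarate, 2–5× drops in the glutamate-derived pool, null
orthologs) rather than derived from the reaction–diffusion model, because
the abundance→γ link is empirical. Labeling curves follow
FC(t) = 0.55·(1 − e^{−λt}) with λ halved in overexpression strains; the
isotopologue vectors mix an unlabeled pool (pure M+0, so FC(0) = 0 exactly)
with a binomially blurred labeled pool, weight-scaled so the realized FC
plateau equals 0.55 despite the blur. All noise is multiplicative
log-normal (mean-preserving, positivity-preserving) at CV 5% by default,
drawn from a single seeded generator in fixed order — identical configs
give identical bytes.

What the generators do *not* emulate: instrument drift and batch effects,
natural-abundance isotope structure, correlated metabolite covariance
beyond the imposed strain effects, droplet-size dispersion, and saturation
kinetics. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to real-data
artifacts.

## Known limitations

* First-order kinetics only; no Michaelis–Menten saturation, single cluster,
  spherical symmetry.
* The empirical ratio→γ calibration is ordering-preserving, not mechanistic.
* The exact test's enumeration grows combinatorially; groups above 8 use the
  normal approximation.
* The in-vivo kinetic preset is a calibrated stand-in for an unavailable
  parameter table; conclusions that depend on its absolute values (rather
  than on model structure) should be re-derived with measured kinetics.
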