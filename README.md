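# clusterflux

Modeling and analysis tools for **cluster-mediated substrate channeling**:
the phenomenon where a high local concentration of an enzyme — here driven by
a protein–protein interaction that condenses isocitrate dehydrogenase (ICD)
into clusters inside phase-separated droplets or the bacterial cytoplasm —
enhances apparent catalytic rate and sequesters the reaction product
(2-oxoglutarate) near the cluster, reshaping flux through the carbon–nitrogen
branchpoint it feeds.

The package is aimed at quantitative biologists studying metabolons and
liquid–liquid phase-separated (LLPS) enzyme assays. It couples:

* **`cluster_model`** — an exact steady-state solution of the coupled
  substrate/product reaction–diffusion equations in a three-region spherical
  basin (cluster radius R₁ ⊂ droplet R₂ ⊂ basin R₀). With the clustering
  excess γ = n₁/n₂ splitting N_total enzyme copies into clustered (n₁) and
  dispersed (n₂) pools,

      D∇²c₀ − k·n(r)·c₀ − α₀(c₀ − c₀*) = 0        (substrate)
      D∇²c₁ + k·n(r)·c₀ − β·c₁        = 0        (product)

  with region-wise constant enzyme density n(r) and k = k_cat/K_M. Each
  region is solved in the modified-Helmholtz basis {sinh(κr)/r, cosh(κr)/r};
  the global solution follows from regularity at r = 0, continuity of value
  and flux at R₁ and R₂, and a zero-flux (or clamped) outer boundary.
  Derived quantities: radial profiles, phase averages, the droplet/bulk
  partition ratio, γ-sweeps with onset/plateau detection, and γ inversion
  from a measured partition ratio.
* **`numeric_oracle`** — an independent conservative finite-volume solver
  (steady and transient) for the same equations, used for cross-validation
  and time courses.
* **`llps_assay`** — droplet-assay analytics: linear calibration, initial-
  rate velocities, percent rate enhancement, droplet/supernatant
  partitioning, and an empirical molar-ratio → γ calibration.
* **`isotope_tracer`** — ¹³C labeling dynamics: mass distribution vectors,
  fractional contribution FC = Σᵢ i·s(i)/n, M+0 decay and FC curves,
  metabolic steady-state detection, and glucose uptake fitting
  (ΔS = (−q/m)·ΔC).
* **`metabolomics_ratios`** — OD normalization, control-relative log fold
  changes, branchpoint metabolite ratios, **exact** two-tailed Mann–Whitney
  tests at small n (full permutation distribution, ties included), and PCA
  scores.
* **`synthetic_data`** — seeded generators for every input above, with
  machine-readable truth records for parameter-recovery testing.

## Worked example

`examples/droplet_assay_analysis.py` generates a synthetic droplet assay
(MDH:ICD molar ratios 1:1 … 500:1, 3 replicates, 5% noise) and analyzes it:

```
endogenous MDH enhancement (% above baseline):
  MDH:ICD  estimate   +-2SE
        0      -0.0     2.9
       10      10.4     3.6
      100     114.4     5.5
      250     175.4    18.0
      500     177.0     6.7

ortholog MDH at 500:1: -1.0% (no specific interaction)
droplet/supernatant product ratio at 40 min, 500:1: 2.12
```

The ICD rate rises ~10% at 10:1 and saturates near 180% above 250:1 while
the product becomes ~2-fold enriched in the droplet phase; orthologous MDH
(no specific interaction, hence no clustering) shows neither effect. The
other scripts in `examples/` walk through the radial steady-state profile,
the γ-sweep with onset/plateau detection, labeling dynamics, and the
branchpoint ratio statistics (each prints a short interpretation line).

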