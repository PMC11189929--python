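# Bundled model parameterizations.
#
# Geometry values are the published radii of the clustering model: for the
# cellular ("in_vivo") setting the cluster radius is R1 = 0.1 um and the
# cytoplasm-sized droplet is R2 = 2 um; for the droplet-assay ("in_vitro")
# setting the mean droplet diameter is ~10 um, i.e. R2 = 5 um.  Basin radii
# R0 set the no-exchange unit volume surrounding each droplet (non-overlapping
# identical basins) and are a package choice: the droplet occupies ~6-12% of
# its basin volume (dilute suspension / dilute culture).
#
# The original supplementary kinetic table is not reproduced in the main
# text.  k is a typical dehydrogenase catalytic efficiency; the remaining
# in-vivo kinetic values (D, alpha0, beta, N_total) were calibrated once,
# within physiologically defensible ranges, against the published model
# prediction that cluster product accumulation commences near gamma = 5 and
# plateaus toward gamma = 50, and then frozen.  Under the package's 5%/95%
# rise thresholds this calibrated preset yields onset ~3 and plateau ~93;
# see docs/methods.md for why the printed (5, 50) pair is not reachable
# under that operational definition.  The in-vitro values describe a dilute
# buffered assay and are order-of-magnitude choices, not fits.

in_vivo:
  geometry:
    R1: 0.1        # um, published cluster radius for the cellular model
    R2: 2.0        # um, published cytoplasm radius (B. subtilis scale)
    R0: 5.0        # um, basin radius (package choice, see header)
  kinetics:
    k: 1.0         # uM^-1 s^-1, typical dehydrogenase kcat/KM
    D: 5.0         # um^2/s, crowded-cytoplasm metabolite diffusivity (calibrated)
    alpha0: 0.001  # 1/s, slow homeostatic substrate replenishment (calibrated)
    beta: 0.5      # 1/s, product consumption by downstream reactions (calibrated)
    c0_star: 100.0 # uM, homeostatic substrate level (order of magnitude)
    N_total: 1.0e6 # copies, enzyme copies per cytoplasm-droplet (calibrated)
  units:
    k: per_uM_per_s

in_vitro:
  geometry:
    R1: 0.25       # um, sub-resolution cluster within an assay droplet
    R2: 5.0        # um, half the ~10 um mean droplet diameter
    R0: 10.0       # um, droplet phase ~12% of the suspension volume
  kinetics:
    k: 1.0         # uM^-1 s^-1, typical dehydrogenase kcat/KM
    D: 300.0       # um^2/s, small-metabolite diffusivity in buffer
    alpha0: 5.0    # 1/s, substrate replenishment (substrate in excess)
    beta: 0.5      # 1/s, effective product removal in the assay
    c0_star: 100.0 # uM, assay substrate scale
    N_total: 60000 # copies per droplet at ~100 nM enzyme in a 10 um droplet
  units:
    k: per_uM_per_s
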