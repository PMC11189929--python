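"""Radial substrate/product profile of a clustered-enzyme droplet.

Solves the three-region reaction-diffusion steady state on the cellular
("in_vivo") preset at strong clustering (gamma = 100) and prints the
concentration profile from the cluster center to the basin edge, plus the
phase-level summary.  The product peaks inside the cluster and decays toward
the bulk; the droplet/bulk ratio quantifies the apparent partitioning.
"""

import numpy as np

import clusterflux as cf

geom, kin = cf.preset("in_vivo")
sol = cf.solve_steady_state(geom, kin, gamma=100.0)

radii = np.array([0.0, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 3.0, geom.R0])
c0, c1 = cf.evaluate_profile(sol, radii)

print(f"geometry: R1={geom.R1} um (cluster)  R2={geom.R2} um (cytoplasm)  "
      f"R0={geom.R0} um (basin), gamma=100")
print(f"{'r (um)':>8} {'substrate (uM)':>16} {'product (uM)':>14}")
for r, s, p in zip(radii, c0, c1):
    print(f"{r:8.2f} {s:16.4f} {p:14.4f}")

pa = cf.phase_averages(sol)
print(f"\nproduct means: cluster {pa.mean_cluster:.4f} uM, "
      f"droplet {pa.mean_droplet:.4f} uM, bulk {pa.mean_bulk:.4f} uM")
print(f"droplet/bulk product ratio: {pa.droplet_bulk_ratio:.3f}")
print("-> the product is enriched inside and near the cluster: high local")
print("   enzyme density outpaces diffusive escape from the droplet.")
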