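"""Cluster-product response as a function of the clustering excess gamma.

Sweeps gamma = n1/n2 (clustered vs dispersed enzyme copies) on the cellular
preset, prints the cluster-center product concentration and the droplet/bulk
partition ratio, and locates where the response starts rising (onset) and
levels off (plateau) using 5%/95% rise thresholds.
"""

import numpy as np

import clusterflux as cf

geom, kin = cf.preset("in_vivo")
gammas = np.concatenate([[0.0], np.geomspace(0.1, 100.0, 28)])
sweep = cf.gamma_sweep(geom, kin, gammas)

print(f"{'gamma':>8} {'c1(0) (uM)':>12} {'droplet/bulk':>13}")
for i in range(0, len(gammas), 4):
    print(f"{gammas[i]:8.2f} {sweep.cluster_center_c1[i]:12.4f} "
          f"{sweep.droplet_bulk_ratio[i]:13.4f}")

op = cf.find_onset_and_plateau(sweep, f_on=0.05, f_pl=0.95)
print(f"\nonset (5% of rise):   gamma = {op.gamma_onset:.2f}")
print(f"plateau (95% of rise): gamma = {op.gamma_plateau:.2f}")
print("-> below the onset, dispersed enzymes dominate the center signal and")
print("   cluster-local substrate depletion offsets the gain; above the")
print("   plateau nearly all copies are clustered and the response saturates.")
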