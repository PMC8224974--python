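"""TSS and element-centred coverage metaprofiles.

The TSS profile averages a coverage track over oriented +/-3 kb promoter
windows (offset 0 = TSS, minus-strand windows reversed).  The element
profile rescales each repeat copy to 100 body bins, exposing the planted
5'-skewed H3K4me1-like enrichment on the SVA-like family.
"""

import numpy as np

from promscape import SimulationConfig, simulate_all
from promscape.profiles import compute_element_profile, compute_tss_profile

ds = simulate_all(SimulationConfig(seed=1))

dbp = ds.dbp_names[0]
mp = compute_tss_profile(ds.tracks[dbp], ds.promoters, ds.genome, flank=3000)
center = mp.mean[2500:3500].mean()
edges = np.concatenate([mp.mean[:500], mp.mean[-500:]]).mean()
print(f"{dbp} TSS profile over {mp.n_anchors} promoters: "
      f"mean coverage {center:.3f} near the TSS vs {edges:.3f} at the edges")

fam = [r for r in ds.repeats if r.family == ds.config.planted_family]
sp = compute_element_profile(ds.tracks["H3K4me1"], fam, ds.genome,
                             flank=5000, body_bins=100, flank_bin_size=50)
print(f"\nH3K4me1 across {sp.n_elements} {ds.config.planted_family} elements:")
print(f"  5' body decile mean {sp.body_mean[:10].mean():.2f} vs "
      f"3' decile {sp.body_mean[-10:].mean():.2f} "
      f"(flank background {sp.flank5_mean.mean():.3f})")
# The ~10x 5'-to-3' gradient recovers the planted asymmetric mark, the kind
# of signature that suggests an element's 5' end acts as a regulatory boundary.
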