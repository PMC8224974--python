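"""Per-family repeat enrichment Z-scores across all DBPs.

Reproduces the planted structure: three designated binder DBPs carry one
peak per copy of the SVA-like family, so their Z-scores against that
family tower over everything else, while decoy families stay near zero.
"""

from promscape import SimulationConfig, simulate_all, build_consensus
from promscape.enrichment import repeat_enrichment_matrix

ds = simulate_all(SimulationConfig(seed=1), with_coverage=False)
sets = [build_consensus(ds.peaksets[d], d) for d in ds.dbp_names]

z, p, _ = repeat_enrichment_matrix(sets, ds.repeats, ds.genome,
                                   by="family", n_perm=200, seed=1)
print("Z-scores (last 5 DBPs x families):")
print(z.tail(5).round(1).to_string())
top = z[ds.config.planted_family].idxmax()
print(f"\nstrongest {ds.config.planted_family} binder: {top} "
      f"(Z = {z.loc[top, ds.config.planted_family]:.1f}, "
      f"planted binders = {ds.family_binders})")
# A Z-score of ~50-80 means the observed overlap count is that many null
# standard deviations above random placement -- unambiguous targeting.
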