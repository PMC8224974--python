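"""Constrained-shuffle permutation test of promoter binding for one DBP.

The null preserves peak count, widths and per-chromosome placement;
only start positions are redrawn uniformly.  Z > 0 with a small p means
the DBP sits on promoters far more often than chance placement allows.
"""

from promscape import SimulationConfig, simulate_all, build_consensus
from promscape.enrichment import permutation_enrichment

ds = simulate_all(SimulationConfig(seed=1), with_coverage=False)
dbp = ds.dbp_names[0]
cs = build_consensus(ds.peaksets[dbp], dbp)
windows = [w.interval for w in ds.promoters]

res = permutation_enrichment(cs, windows, ds.genome, n_perm=500, seed=1,
                             feature_set="promoters")
print(f"{dbp}: {res.observed}/{res.n_peaks} peaks overlap a promoter window")
print(f"null: {res.null_mean:.1f} +/- {res.null_sd:.1f} over 500 shuffles")
print(f"Z = {res.z:.1f}, empirical p = {res.p_empirical:.4g}, "
      f"Fisher p = {res.p_fisher:.3g} -> {res.direction}")
# Promoter-planted peaks dominate this DBP, so the observed count sits far
# above anything the constrained shuffle produces.
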