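"""Spatial correlation of nanopore clusters before/after photobleaching.

Simulates immobile-cluster maps in which 9.2% of clusters persist at the
same position (jittered by 22.5 nm) while the rest re-assemble at random
positions, then runs particle image cross-correlation spectroscopy:
the intercept of the linear regime of the cumulative correlation curve
gives the correlated fraction, the short-range rise its length scale, and
a Monte Carlo null assesses significance at the matched cluster density.
"""

from poretrack import piccs, simkit

cfg = simkit.AcquisitionConfig(rng_seed=11)
a, b, truth = simkit.simulate_point_pattern_pair(
    density_per_um2=2.0, alpha_true=0.092, displacement_sigma_nm=22.5,
    area_um2=2500.0, cfg=cfg,
)
print(f"pattern A: {len(a)} clusters, pattern B: {len(b)} clusters "
      f"on a 50 x 50 um field")

res = piccs.run_piccs(a, b, r_max_um=0.5, bounds_um=(0.0, 50.0))
print(f"correlated fraction alpha = {res.alpha * 100:.1f} % (truth 9.2 %)")
print(f"correlation length sigma_c = {res.sigma_c_um * 1e3:.1f} nm (truth 22.5 nm)")
print(f"background cluster density = {res.rho_per_um2:.2f} um^-2")

lo, hi = piccs.background_null(a, b, n_mc=200, bounds_um=(0.0, 50.0), seed=1)
print(f"95% null interval for alpha under CSR: [{lo * 100:.2f}, {hi * 100:.2f}] %")
print("-> alpha far above the null bound: a significant fraction of clusters")
print("   kept their position; the rest disassembled and re-formed elsewhere.")
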