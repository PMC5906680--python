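"""Counting nanopores per immobile cluster by photobleaching steps.

Simulates intensity traces of spots containing 1-4 fluorophore-labelled
pores (exponential bleaching lifetimes, Gaussian read noise at 10% of the
single-molecule level), segments each trace with the t-test/MDL
change-point scheme and counts irreversible bleaching steps after the
dwell and lag filters.  The step-count histogram estimates the oligomer
distribution of the clusters.
"""

import numpy as np

from poretrack import simkit, stepcount

rng = np.random.default_rng(0)
weights = [0.6, 0.25, 0.1, 0.05]          # mostly monomers, some oligomers
hist: dict[int, int] = {}
true_hist: dict[int, int] = {}
traces, fits = [], []
for i in range(100):
    k = int(rng.choice([1, 2, 3, 4], p=weights))
    cfg = simkit.AcquisitionConfig(rng_seed=1000 + i)
    trace, _ = simkit.simulate_bleach_trace(k, cfg, noise_sigma=50.0)
    fit = stepcount.segment(trace, fp_limit=0.02, min_separation=70.0)
    steps = stepcount.count_bleach_steps(fit, min_dwell=50, max_lag=6)
    hist[steps] = hist.get(steps, 0) + 1
    true_hist[k] = true_hist.get(k, 0) + 1
    traces.append(trace)
    fits.append(fit)

print("steps counted | spots   (true fluorophores | spots)")
for k in sorted(set(hist) | set(true_hist)):
    print(f"{k:13d} | {hist.get(k, 0):5d}   ({k} | {true_hist.get(k, 0)})")

reg = stepcount.steps_vs_intensity(traces, fits)
print(f"first-frame intensity vs step count: slope = {reg['slope']:.0f} photons/step, "
      f"r = {reg['r']:.3f}")
print("-> a slope near the 500-photon single-molecule level and r close to 1")
print("   indicate consistent counting across oligomer sizes.")
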