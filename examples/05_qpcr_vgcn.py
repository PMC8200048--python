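"""Absolute viral genome quantification from a free-ITR qPCR plate.

Fits the standard curve from a 10-fold plasmid dilution series (1e8..1e4
copies, triplicate Cq), reads unknown blood samples off the curve as copies
per 10 ng template and per diploid genome, screens the cohort with a Grubbs
outlier test and checks a blood-vs-tissue correlation by linear regression.
"""

import numpy as np

from aavquant import (
    GENOMES_PER_10NG,
    fit_standard_curve,
    grubbs_test,
    linear_regression,
    quantify_vgcn,
    simulate_cq,
)

rng = np.random.default_rng(1)
dilutions = [1e8, 1e7, 1e6, 1e5, 1e4]
cq_std = simulate_cq(dilutions, slope=-3.40, intercept=36.8, sd=0.08, rng=rng)
curve = fit_standard_curve(dilutions, [list(row) for row in cq_std])
print(f"standard curve: slope {curve.slope:.3f} Cq/log10, intercept {curve.intercept:.2f}, "
      f"R^2 {curve.r_squared:.4f}")
print(f"amplification efficiency: {curve.efficiency_pct:.1f}% "
      "(100% would be a perfect doubling, slope -3.322)")

# eight mice dosed identically: blood VGCn around 1e6 copies / 10 ng
true_loads = rng.lognormal(np.log(1.0e6), 0.15, size=8)
results = []
for i, load in enumerate(true_loads):
    cq = simulate_cq(load, slope=curve.slope, intercept=curve.intercept, sd=0.1, rng=rng)[0]
    results.append(quantify_vgcn(list(cq), curve, sample_id=f"mouse_{i + 1}"))

print(f"\n{'sample':10}{'mean Cq':>9}{'VGCn/10ng':>13}{'VGCn/genome':>13}")
for r in results:
    print(f"{r.sample_id:10}{r.cq_mean:>9.2f}{r.vgcn_per_10ng:>13.3g}{r.vgcn_per_genome:>13.1f}")
print(f"(per-genome uses {GENOMES_PER_10NG:.0f} diploid genomes per 10 ng, 6.0 pg/genome)")

loads = [r.vgcn_per_10ng for r in results]
idx, g, crit = grubbs_test(loads, alpha=0.05)
verdict = f"sample index {idx} is an outlier" if idx is not None else "no outliers"
print(f"\nGrubbs screen: G = {g:.2f} vs critical {crit:.2f} -> {verdict}")

# blood VGCn vs an uncorrelated downstream tissue measure
tissue = rng.lognormal(np.log(3e3), 0.3, size=8)
slope, intercept, r2, p = linear_regression(loads, list(tissue))
print(f"blood-vs-tissue regression: R^2 {r2:.3f}, slope p = {p:.3f} "
      f"({'no' if p > 0.05 else 'a'} significant correlation)")
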