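"""Ratio spectra: which body ratios dominate a shape PC, and which are
allometric (change with body size)?

A ratio spectrum orders the variables by their coefficient on an axis; only
ratios formed from variables at the *opposite ends* matter for that axis.
Horizontal bootstrap CIs say how stable each position is.
"""

from mra import (allometry_ratio_spectrum, drop_variables, impute_missing,
                 pca_ratio_spectrum, shape_decompose, shape_pca,
                 size_shape_scatter)
from mra.synthetic import demo_scenario, simulate_measurements

raw, _ = simulate_measurements(demo_scenario(seed=42))
table, _ = impute_missing(drop_variables(raw, ["gst.b"]), seed=42)
shape = shape_decompose(table.subset_groups(["calandrae", "quinarius"]))
pca = shape_pca(shape)

spec = pca_ratio_spectrum(pca, 1, shape, n_boot=1000, level=0.68, seed=42)
print("PCA ratio spectrum of PC1 (top and bottom = the dominant ratio):")
print(spec.to_frame().round(3).to_string())
print(f"=> the ratio {spec.ordering[-1]} : {spec.ordering[0]} dominates PC1")

allo = allometry_ratio_spectrum(shape, n_boot=1000, level=0.68, seed=42)
print(f"\nallometry spectrum extremes: {allo.ordering[-1]} vs "
      f"{allo.ordering[0]} (the most size-dependent ratio)")

_, r = size_shape_scatter(pca, shape, 1)
print(f"isosize vs PC1 Pearson r = {r:.2f} "
      "(|r| well above 0 indicates allometric shape change)")
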