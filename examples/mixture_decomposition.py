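"""Resolve small/medium/large populations from a pooled size distribution.

Draws an all-point sample from a three-population generator (think mEPSC
peak amplitudes in pA, or synaptic-puncta surface areas in um^2), bins it
with the Freedman-Diaconis rule, decomposes the density into a sum of
Gaussians with chi-square model selection, and reports the component area
fractions, the inter-population cutoffs, and the size-class proportions.
"""

import numpy as np

from axotrace import (
    MixtureSpec,
    build_histogram,
    classify_sizes,
    component_fractions,
    sample_mixture,
    select_model,
    size_cutoffs,
)

# three populations of negative-going amplitudes, fractions 31/41/28 %
spec = MixtureSpec(
    components=((0.31, -5.0, 2.0), (0.41, -12.0, 2.0), (0.28, -22.0, 2.0)),
    n=5000,
    seed=0,
)
samples = sample_mixture(spec)

hist = build_histogram(samples)
fit, trail = select_model(hist)

print(f"bin width (Freedman-Diaconis): {hist.bin_width:.3f} pA")
print("chi-square trail:", "  ".join(f"k={f.k}: {f.chi_square:.2f}" for f in trail))
print(f"accepted model: {fit.k} Gaussians (adjusted r^2 = {fit.adjusted_r2:.4f})")
for comp, frac in zip(fit.components, component_fractions(fit)):
    print(f"  center {comp.center:7.2f} pA  width {comp.width:5.2f}  area fraction {100 * frac:.1f} %")

cuts = size_cutoffs(fit)
print(f"cutoffs between populations: {cuts[0]:.2f}, {cuts[1]:.2f} pA")
labels, props = classify_sizes(samples, cuts, use_magnitude=True)
print("size-class proportions:", ", ".join(f"{k} {100 * v:.1f} %" for k, v in props.items()))
# The chi-square trail drops sharply up to the true component count and then
# flattens; the accepted fractions recover the generating 31/41/28 split.
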