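"""How demographic history shapes the projection curve.

Runs the canonical one-population scenario variants for a test genome
sampled 1000 generations ago and prints the projection at low, middle and
high panel frequencies.  Size changes in the reference population bend the
curve in characteristic ways: an expansion depresses rare-allele sharing, a
decline inflates it, and a bottleneck produces a humped curve.
"""

import numpy as np

from projana import ScenarioSpec, mpv, run_scenario_grid

specs = [ScenarioSpec("OPM", v, 1000) for v in "ABCDE"]
curves = run_scenario_grid(specs, num_sites=50_000, seed=2, expected=True)

labels = {
    "A": "constant size",
    "B": "5% pulse from unsampled sister",
    "C": "expansion 500->5000 at 750 ga",
    "D": "decline 5000->500 at 750 ga",
    "E": "bottleneck 500-1000 ga",
}
print(f"{'variant':38s} {'w(x<=0.1)':>10s} {'w(mid)':>8s} {'w(x>0.9)':>9s} {'MPV':>7s}")
for spec, curve in curves.items():
    w, x = curve.w, curve.x
    print(
        f"{spec.variant} {labels[spec.variant]:36s} "
        f"{np.nanmean(w[x <= 0.1]):10.3f} "
        f"{np.nanmean(w[(x > 0.4) & (x <= 0.6)]):8.3f} "
        f"{np.nanmean(w[x > 0.9]):9.3f} "
        f"{mpv(curve):7.3f}"
    )

print(
    "\nA and B are flat near exp(-0.1) = 0.90 (a small pulse from an"
    "\nunsampled population leaves no mark); C sags at low x, D rises there,"
    "\nand E rises to an interior hump before falling.  MPV is the mean"
    "\nprojection over categories with x > 0.5."
)
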