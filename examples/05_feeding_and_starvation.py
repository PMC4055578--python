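"""Feeding success and starvation risk over the 6-day hunger cycle.

Hosts are placed singly and evenly at a density per km^2 of habitat;
flies feed only on them (probing response rising 0.1 -> 0.6 over the
cycle).  Low densities in narrow bands put hosts kilometres apart, so
the band is modelled as a long thin grid with reflecting ends.
"""

import warnings

from glossim import (feeding_success, long_band_for_density, make_block,
                     starvation_percent, target_efficacy)

warnings.simplefilter("ignore", UserWarning)

band = long_band_for_density(1, 100, n_baits=20)
block = make_block(200)
print("4-day feeding success, lizards at 100/km^2:")
print(f"  10 m band, singly: {feeding_success(band, 'lizard', 100):.1f}%")
print(f"  large block, singly: {feeding_success(block, 'lizard', 100):.1f}%")
print(f"  large block, groups of 4: "
      f"{feeding_success(block, 'lizard', 100, group_size=4):.1f}%")

kband = long_band_for_density(1, 16, n_baits=4)
print("\nstarvation risk if still unfed after day 2 (kudu at 16/km^2):")
for mult, label in ((1 / 3, "2000"), (1.0, "6000"), (3.0, "18000")):
    p = starvation_percent(kband, "kudu", 16, 2, mult)
    print(f"  10 m band, {label:>5s} steps/cycle: {p:.1f}%")
print(f"  large block, 6000 steps/cycle: "
      f"{starvation_percent(block, 'kudu', 16, 2):.1f}%")

print("\ntiny odorless targets at 8/km^2, kill per cycle:")
print(f"  10 m band: {target_efficacy(long_band_for_density(1, 8, 4), 'tiny_target', 8):.1f}%")
print("-> in restricted habitat flies cannot afford to be choosy: "
      "unfed flies face near-certain starvation unless they accept "
      "whatever host they meet.")
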