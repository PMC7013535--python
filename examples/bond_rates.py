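"""Single-bond kinetics: catch vs slip dissociation and separation-dependent binding.

Builds the default bond parameter set and prints the force dependence of
the two-pathway (catch) off-rate next to the Bell (slip) rate, plus the
association rate over the gap width.
"""

import numpy as np

import catchroll as cr
from catchroll.calibrate import off_rate_minimum

bond = cr.BondParams()
slip = bond.comparison_slip()

print("force (pN)   koff catch (1/s)   koff slip (1/s)")
for f in [0.0, 2.0, 5.0, 10.0, 20.0, 40.0]:
    print(f"{f:10.1f} {cr.off_rate(f, bond):18.3f} {cr.off_rate(f, slip):17.3f}")

f_min, k_min = off_rate_minimum(bond)
print(f"\ncatch off-rate minimum: {k_min:.2f} 1/s at {f_min:.1f} pN")
print("-> a moderate pull *stabilizes* the catch bond (its off-rate drops "
      f"{cr.off_rate(0.0, bond) / k_min:.1f}-fold from zero force), while the "
      "slip bond only ever destabilizes.")

print("\ngap delta (nm)   kon (1/s)")
for d in bond.rest_separation + np.array([0.0, 2.0, 5.0, 10.0]):
    print(f"{d:13.1f} {cr.on_rate(d, bond):11.4f}")
print("-> binding is confined to ~one thermal stretch "
      f"({bond.thermal_length:.1f} nm) of the contact gap.")
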