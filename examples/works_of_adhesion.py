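"""Advancing and receding works of adhesion versus rolling speed.

Integrates the mean-field bond density at the moving leading and
trailing contact edges and prints the two works of adhesion, their
common quasi-static limit, and the speed at which the receding work
peaks (the speed the rolling cell resists best).
"""

import numpy as np

import catchroll as cr

bond = cr.BondParams()
kin = cr.EdgeKinematics()

w_qs = cr.quasi_static_work(bond, kin)
print(f"quasi-static work of adhesion wQS = {w_qs:.4f} uJ/m^2")

curve = cr.work_curves(kin, bond, vc_grid=np.geomspace(1e-2, 1e4, 120))
print("\nvc (um/s)   wa (uJ/m^2)   wr (uJ/m^2)")
for vc in [0.1, 1.0, 10.0, 100.0, 1000.0]:
    print(f"{vc:9.1f} {curve.wa_of(vc):12.4f} {curve.wr_of(vc):12.4f}")

print(f"\nreceding work peaks at v* = {curve.v_star:.2f} um/s "
      f"(wr_max = {curve.wr.max():.2f} uJ/m^2, {curve.wr.max() / w_qs:.0f}x wQS).")
print("-> slow rolling lets stretched bonds escape before storing energy; "
      "fast rolling forms too few bonds; the maximum in between is what "
      "pins the cell against the flow.")
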