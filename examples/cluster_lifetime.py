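"""Mean lifetime of a 10-bond cluster under force: catch vs slip.

Solves the birth--death master equation (via the closed-form mean first
passage time) for a cluster whose bonds all share the same gap, and
locates the force window where catch bonds outlive slip bonds.
"""

import numpy as np

import catchroll as cr

Nt = 10
bond = cr.BondParams()
curves = cr.lifetime_vs_force(np.linspace(0.0, 30.0, 121), Nt, bond)

print(f"cluster of {Nt} bonds, per-bond force sweep:")
print("f (pN)   tau catch (s)   tau slip (s)")
for f in [0.0, 2.0, 5.0, 10.0, 15.0, 25.0]:
    row = curves.iloc[(curves["f_pN"] - f).abs().argmin()]
    print(f"{row.f_pN:6.1f} {row.tau_catch_s:15.3g} {row.tau_slip_s:14.3g}")

tau_c = curves["tau_catch_s"].to_numpy()
i = int(np.argmax(tau_c))
print(f"\ncatch cluster lives longest ({tau_c[i]:.2f} s) at "
      f"{curves['f_pN'][i]:.1f} pN — force *strengthens* the cluster up to there.")
diff = curves["tau_slip_s"].to_numpy() - tau_c
j = int(np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))[0])
print(f"slip bonds outlive catch bonds below ~{curves['f_pN'][j]:.1f} pN "
      "(the stronger slip barrier wins when nothing pulls).")
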