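"""Unit conventions and conversion constants.

Bond-scale quantities are kept in a canonical (pN, nm, s) system; cell
speeds are in μm/s; shear rates in 1/s; works of adhesion are reported
in μJ/m².  All cross-system conversions are centralized here.

Derivations:
    1 μm/s   = 1000 nm/s
    1 pN/nm  = 1e-12 N / 1e-9 m = 1e-3 N/m = 1e-3 J/m² = 1000 μJ/m²
    η[Pa·s] · v[μm/s] = 1e-6 N/m = 1 μJ/m²   (so v̄ = η·v/wQS is
      dimensionless with η in Pa·s, v in μm/s, wQS in μJ/m²)
"""

# thermal energy at T ≈ 300 K; configurable through BondParams.kBT
KBT_PN_NM = 4.14  # pN·nm

UM_PER_S_TO_NM_PER_S = 1.0e3

# a line density of work, pN/nm (= pN·nm per nm² of swept area), in μJ/m²
PN_PER_NM_TO_UJ_PER_M2 = 1.0e3

# bond surface density: 1 μm⁻² = 1e-6 nm⁻²
PER_UM2_TO_PER_NM2 = 1.0e-6
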