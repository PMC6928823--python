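"""Physical constants and the unit conventions used throughout the package.

Working units: millivolt (mV), millisecond (ms), micromolar (uM),
nanometre (nm) for channel-sensor distances, picoampere (pA),
picosiemens (pS), picofarad (pF), femtocoulomb (fC = pA*ms).

All unit conversions live here so that every module agrees on them.
"""

# Faraday constant, C/mol
FARADAY = 96485.33212

#: pS * mV -> pA  (1 pS * 1 mV = 1e-15 A = 1e-3 pA)
PS_MV_TO_PA = 1e-3

#: nm -> um
NM_TO_UM = 1e-3

#: mol/m^3 -> uM  (1 mol/m^3 = 1 mM = 1000 uM)
MOL_PER_M3_TO_UM = 1e3

#: pA -> A
PA_TO_A = 1e-12

#: um^2/ms -> m^2/s  (1e-12 m^2 / 1e-3 s)
UM2_PER_MS_TO_M2_PER_S = 1e-9

#: nm -> m
NM_TO_M = 1e-9
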