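"""Unit conversion constants.

SI is used internally (Pa·s, m, m³/s); bench units (cP, μm, μL/hr, mm/s)
are converted once at the interfaces.
"""

CP_TO_PA_S = 1e-3
PA_S_TO_CP = 1e3

UM_TO_M = 1e-6
M_TO_UM = 1e6

UL_PER_HR_TO_M3_S = 1e-9 / 3600.0
M3_S_TO_UL_PER_HR = 3600.0e9

M_S_TO_MM_S = 1e3
MM_S_TO_M_S = 1e-3
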