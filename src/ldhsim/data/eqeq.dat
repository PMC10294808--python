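# Charge-equilibration parameters, version 1.
# Per-element electronegativity chi [eV] and idempotential (hardness) J [eV/e]
# from the published QEq parameter set (Rappe & Goddard 1991).
# element  chi[eV]  J[eV]
H    4.528   13.8904
C    5.343   10.1260
N    6.899   11.7600
O    8.741   13.3640
Na   2.843    4.5920
Mg   3.951    7.3860
S    6.928    8.9720
Cl   8.564    9.8920
Fe   3.760    8.2800
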