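# UFF Lennard-Jones nonbonded parameters (Rappe et al. 1992), version 1.
# label  x_i[A]  D_i[kcal/mol]
# x_i is the van der Waals minimum distance, D_i the well depth.
# UFF LJ parameters depend only on the element (not hybridisation); one
# representative label per element is kept here.
H_      2.886   0.044
C_3     3.851   0.105
N_3     3.660   0.069
O_3     3.500   0.060
Na      2.983   0.030
Mg3+2   3.021   0.111
S_3+4   4.035   0.274
Cl      3.947   0.227
Fe3+2   2.912   0.013
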