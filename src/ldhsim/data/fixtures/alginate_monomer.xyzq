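21
name=alginate_monomer formula=C6H8O7-2 net_charge=-2 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
O -2.343976 -1.954476 0.291785 -0.36889731
C -1.347243 -1.049167 -0.193060 0.14519013
O -0.056861 -1.645891 -0.099425 -0.34197212
C 0.985628 -0.796782 -0.665599 0.12816807
C 2.353952 -1.533012 -0.550727 0.07317609
O 2.745907 -2.112942 -1.616077 -0.54719642
O 2.950789 -1.498584 0.568723 -0.54719642
C 1.043528 0.567812 0.032256 0.11057332
O 1.876019 1.518526 -0.668095 -0.38732580
C -0.362251 1.193840 0.084078 0.07520088
O -0.334817 2.410830 0.862349 -0.39124638
C -1.392380 0.228973 0.698480 -0.04420077
O -2.605076 0.797278 0.681030 -0.84645183
H -2.893849 -1.328916 0.809320 0.21331813
H -1.583982 -0.840085 -1.244697 0.09098214
H 0.772765 -0.661655 -1.734757 0.06982278
H 1.438059 0.485608 1.051987 0.06597271
H 1.670345 2.355162 -0.208834 0.21073347
H -0.655973 1.500941 -0.930674 0.06195453
H -1.276239 2.428119 1.152579 0.21053310
H -0.984346 -0.065582 1.679358 0.01886169
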