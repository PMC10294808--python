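3
name=water formula=H2O net_charge=0 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
O -0.239071 -0.308876 0.000000 -0.41150952
H 0.718129 -0.308876 0.000000 0.20575476
H -0.479058 0.617751 0.000000 0.20575476
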