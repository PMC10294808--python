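1
name=sodium formula=Na+1 net_charge=1 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
Na 0.000000 0.000000 0.000000 1.00000000
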