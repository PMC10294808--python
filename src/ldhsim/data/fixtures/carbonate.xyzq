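4
name=carbonate formula=CO3-2 net_charge=-2 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
C 0.000000 0.000000 0.000000 -0.04308844
O 1.284000 0.000000 0.000000 -0.65230385
O -0.642000 1.111977 0.000000 -0.65230385
O -0.642000 -1.111977 0.000000 -0.65230385
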