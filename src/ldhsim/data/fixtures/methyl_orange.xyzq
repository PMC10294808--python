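35
name=methyl_orange formula=C14H14N3O3S- net_charge=-1 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
C -5.634585 -1.417256 -0.399961 0.00610758
N -4.967961 -0.168414 -0.035251 -0.37765940
C -5.620516 1.052763 -0.504522 0.00610758
C -3.574050 -0.169570 0.115208 0.03620609
C -2.838868 -1.359335 0.267977 -0.03656596
C -1.444340 -1.363687 0.429392 -0.03247270
C -0.725164 -0.172498 0.447516 0.08581082
C -1.432339 1.023518 0.332807 -0.03247270
C -2.826710 1.020962 0.171512 -0.03656596
N 0.667338 -0.206262 0.637410 -0.15057543
N 1.257708 0.325600 -0.328958 -0.15057666
C 2.654258 0.280999 -0.149897 0.08574333
C 3.281804 0.899150 0.944115 -0.03327778
C 4.672214 0.870176 1.076670 -0.04244319
C 5.439772 0.232793 0.098998 0.05447219
C 4.833876 -0.386631 -0.996848 -0.04244319
C 3.442850 -0.352447 -1.120407 -0.03327778
S 7.243509 0.169145 0.275036 0.12392653
O 7.587042 -1.102918 -0.355487 -0.23738112
O 7.432999 0.212464 1.722695 -0.23738112
O 7.652736 1.366419 -0.452337 -0.74403576
H -5.262575 -1.798768 -1.357320 0.04560021
H -5.504805 -2.178400 0.376796 0.04560021
H -6.716619 -1.274344 -0.499440 0.04560021
H -5.243075 1.348991 -1.489548 0.04560021
H -5.483584 1.874662 0.206294 0.04560021
H -6.703896 0.913643 -0.594271 0.04560021
H -3.329867 -2.327105 0.269951 0.06454289
H -0.917299 -2.307654 0.541455 0.06469652
H -0.896788 1.968575 0.370538 0.06469652
H -3.307347 1.990905 0.095193 0.06454289
H 2.684072 1.403906 1.697107 0.06466199
H 5.161739 1.339835 1.925963 0.06367528
H 5.448814 -0.883985 -1.742596 0.06367528
H 2.969657 -0.825230 -1.975790 0.06466199
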