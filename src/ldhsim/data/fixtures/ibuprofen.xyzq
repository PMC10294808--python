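33
name=ibuprofen formula=C13H18O2 net_charge=0 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
C -4.539207 1.061451 -0.237970 -0.06245589
C -3.125137 0.665828 0.194339 -0.04307413
C -3.200954 -0.357424 1.330436 -0.06245589
C -2.340676 0.126563 -1.017855 -0.02556406
C -0.871371 -0.091349 -0.745959 -0.04774417
C -0.354289 -1.385198 -0.617974 -0.05873453
C 1.004352 -1.585553 -0.359932 -0.05791038
C 1.877433 -0.496398 -0.228900 -0.03408770
C 1.354424 0.798841 -0.352294 -0.05791038
C -0.004042 0.998621 -0.610386 -0.05873453
C 3.348658 -0.734525 0.059747 0.07885936
C 4.264722 -0.103455 -0.992367 -0.04776532
C 3.716151 -0.318865 1.472845 0.31018535
O 3.620791 -1.018306 2.470590 -0.25175845
O 4.138096 0.956401 1.589703 -0.48078850
H -5.091783 0.199769 -0.627874 0.02331909
H -4.506826 1.826636 -1.020780 0.02331909
H -5.103641 1.472605 0.605728 0.02331909
H -2.630301 1.566176 0.580099 0.03003988
H -3.800596 0.030036 2.161221 0.02331909
H -3.658440 -1.293439 0.992335 0.02331909
H -2.206844 -0.587385 1.726244 0.02331909
H -2.422641 0.831243 -1.856388 0.03186028
H -2.796927 -0.806915 -1.372930 0.03186028
H -1.007634 -2.249817 -0.711459 0.06257101
H 1.372822 -2.604324 -0.257833 0.06259710
H 1.998982 1.668843 -0.243370 0.06259710
H -0.382219 2.014326 -0.702946 0.06257101
H 3.549367 -1.814335 0.016142 0.04690926
H 4.166170 0.986632 -1.034434 0.02424255
H 5.314582 -0.326191 -0.771347 0.02424255
H 4.038027 -0.494843 -1.990343 0.02424255
H 4.278951 1.064351 2.553914 0.29629110
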