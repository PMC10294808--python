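56
name=tetracycline formula=C22H24N2O8 net_charge=0 charge_scheme=PEOE-Gasteiger(substitute-for-DFT) geometry=ETKDG+MMFF94
C 2.668180 -2.427006 -0.948701 -0.03115951
C 2.205214 -1.755455 0.351914 0.09476284
O 1.917254 -2.799971 1.291454 -0.38478590
C 3.335285 -0.881153 0.889105 -0.00127422
C 4.359425 -1.441839 1.677771 -0.05512645
C 5.406303 -0.655914 2.160564 -0.05816208
C 5.459226 0.699485 1.850524 -0.01942568
C 4.472450 1.266095 1.049163 0.12663409
O 4.618055 2.600279 0.776206 -0.50717223
C 3.407328 0.489077 0.564719 0.07017275
C 2.383723 1.116003 -0.309430 0.19650243
O 2.544986 2.256902 -0.740772 -0.28866169
C 1.158796 0.333414 -0.639416 0.04757658
C 0.327832 0.748441 -1.620334 0.13976597
O 0.545021 1.893677 -2.364291 -0.50826397
C -0.920494 -0.034072 -1.984145 0.18951444
O -0.507500 -0.958625 -3.006915 -0.37386443
C -2.043497 0.833618 -2.584015 0.21100729
O -2.130228 0.960674 -3.808156 -0.28998138
C -2.978952 1.524899 -1.651760 0.12475214
C -3.937221 2.529508 -2.193934 0.25545084
N -4.089096 3.671816 -1.463786 -0.36537516
O -4.576956 2.360946 -3.223810 -0.26926008
C -2.974611 1.193904 -0.342887 0.12626195
O -3.801441 1.867719 0.551444 -0.50965062
C -2.091033 0.108694 0.271022 0.07421935
N -2.714688 -0.721686 1.314755 -0.29927480
C -4.036800 -1.270256 1.051056 -0.01295072
C -2.483336 -0.335246 2.696390 -0.01295072
C -1.462971 -0.835978 -0.795393 0.02614062
C -0.324421 -1.719872 -0.229955 -0.03448958
C 0.915249 -0.898608 0.201881 0.02453984
H 3.595211 -2.991309 -0.786929 0.02635323
H 2.858186 -1.702405 -1.747295 0.02635323
H 1.941241 -3.161413 -1.308635 0.02635323
H 1.901289 -2.411367 2.183060 0.21136953
H 4.355056 -2.506548 1.911032 0.06269901
H 6.188553 -1.103536 2.769503 0.06241796
H 6.277658 1.313342 2.218541 0.06620737
H 3.932324 2.860514 0.122758 0.29312943
H 1.360064 2.340415 -2.042178 0.29277310
H -0.548865 -0.443582 -3.841551 0.21217198
H -4.844012 4.279755 -1.750448 0.15946846
H -3.832798 3.663929 -0.483667 0.15946846
H -3.837490 1.338954 1.367725 0.29269500
H -1.275328 0.667477 0.747310 0.05558050
H -4.123885 -1.653464 0.029628 0.03941846
H -4.834794 -0.538413 1.209099 0.03941846
H -4.231812 -2.120529 1.714389 0.03941846
H -2.759541 -1.151131 3.373955 0.03941846
H -1.420059 -0.140005 2.874234 0.03941846
H -3.047426 0.551672 2.996669 0.03941846
H -2.234498 -1.520500 -1.176704 0.03633772
H -0.684114 -2.314243 0.618624 0.02789529
H -0.053569 -2.451098 -0.998731 0.02789529
H 0.667528 -0.525987 1.209344 0.03884852
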