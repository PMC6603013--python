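compound,a1670,a2130,a2330,a2460
Benzene,0.4410,0.3746,,2.0124
Ortho-xylene,0.2851,0.3598,1.0287,0.6920
Meta-xylene,0.2926,0.3456,1.0546,1.0973
Para-xylene,0.3156,0.4980,1.0237,1.1597
Toluene,0.3122,0.4169,0.4775,1.1594
Ethylbenzene,0.3082,0.3963,0.6867,1.2853
Mesitylene,0.4017,0.3846,1.6218,1.0621
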