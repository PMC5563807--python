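model,class,proportion
PostLactation1,0-6m,0.05
PostLactation1,6-15m,0.35
PostLactation1,15-26m,0.15
PostLactation1,26-36m,0.12
PostLactation1,3-6y,0.10
PostLactation1,6-8y,0.13
PostLactation1,>8y,0.10
PostLactation2,0-6m,0.08
PostLactation2,6-15m,0.30
PostLactation2,15-26m,0.18
PostLactation2,26-36m,0.14
PostLactation2,3-6y,0.08
PostLactation2,6-8y,0.12
PostLactation2,>8y,0.10
IntenseMilk,0-6m,0.45
IntenseMilk,6-15m,0.20
IntenseMilk,15-26m,0.10
IntenseMilk,26-36m,0.08
IntenseMilk,3-6y,0.07
IntenseMilk,6-8y,0.06
IntenseMilk,>8y,0.04
Meat,0-6m,0.04
Meat,6-15m,0.08
Meat,15-26m,0.10
Meat,26-36m,0.14
Meat,3-6y,0.38
Meat,6-8y,0.16
Meat,>8y,0.10
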