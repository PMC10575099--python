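frequency_khz,glucose,lactate,cortisol
30,0.225,0.378,0.225
40,0.378,0.378,0.378
50,0.558,0.558,0.558
60,0.225,0.558,0.225
70,0.791,0.991,0.791
80,0.991,0.991,0.991
90,0.991,0.991,0.991
100,0.991,0.991,0.991
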