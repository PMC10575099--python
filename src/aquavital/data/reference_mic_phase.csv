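frequency_khz,glucose,lactate,cortisol
30,0.5900,0.5577,0.5900
40,0.5577,0.5900,0.5577
50,0.5900,0.5900,0.5900
60,0.5900,0.5900,0.5900
70,0.9911,0.9911,0.9911
80,0.9911,0.9911,0.9911
90,0.9911,0.9911,0.9911
100,0.4789,0.5789,0.3789
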