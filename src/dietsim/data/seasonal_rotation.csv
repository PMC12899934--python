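season,animal,dairy,fruit,grain,legume,nuts,oil,vegetable
1,0.0,0.0,-0.03,0.06,0.0,0.0,0.0,-0.03
2,0.0,0.0,-0.01,-0.03,0.0,0.0,0.0,0.04
3,0.0,0.0,0.05,-0.08,0.0,0.0,0.0,0.03
4,0.0,0.0,0.03,-0.03,0.0,0.0,0.0,0.0
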