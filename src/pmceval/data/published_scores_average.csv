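X1,X2,X3,X4,X5,X6,X7,X8,X9,pmc
0.661272727,0.942,0.25,0.963636364,0.557818182,0.643393939,0.677818182,0.547515152,0.614545455,5.858
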