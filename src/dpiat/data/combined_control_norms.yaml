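mean: 0.082
sd: 0.405
n: 180
label: combined neurotypical controls
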