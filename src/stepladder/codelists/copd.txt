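H3...
H31..
H32..
H3z..
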