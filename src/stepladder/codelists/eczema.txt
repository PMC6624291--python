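M11..
M111.
M112.
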