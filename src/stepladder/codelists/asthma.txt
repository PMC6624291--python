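H33..
H330.
H331.
H332.
H333.
H33z.
173A.
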