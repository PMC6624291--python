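66YJ.
66YK.
66YQ.
661M1
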