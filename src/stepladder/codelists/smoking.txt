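137..
137R.
137S.
137L.
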