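H13..
H130.
H131.
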