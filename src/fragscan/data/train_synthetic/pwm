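rev_start 0.000000 0.000000 1.000000
rev_stop 0.000000 0.000000 1.000000
start 0.000000 0.000000 1.000000
stop 0.000000 0.000000 1.000000
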