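noncoding_to_gene 0.001000
gene_to_stop 0.010000
match_to_insert 0.002500
insert_continue 0.100000
match_skip 0.002500
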