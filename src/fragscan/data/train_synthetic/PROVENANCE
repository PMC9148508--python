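Synthetic default training data generated by scripts/make_default_training.py
(seed 20240601); not trained on real genomes. Substitute a real FGS-format
training directory with the -r option for production use.
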