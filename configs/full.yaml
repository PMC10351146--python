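# Full-scale configuration: the complete breeding-program design.
# 29 chromosomes x 1800 loci, 12,000 animals per generation, 120 sires under
# pedigree selection, 40 under OCS. A full run takes many CPU-hours; use
# desk.yaml for exploratory work.
scale: 1.0
master_seed: 1
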