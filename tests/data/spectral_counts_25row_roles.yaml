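# Column roles for the synthetic 25-row spectral-count fixture.
accession: Accession
gene: Gene
samples:
  bait_rep1:
    role: bait
    peptides: Pep_bait
    counts: TSC_bait
  control_rep1:
    role: control
    peptides: Pep_ctrl
    counts: TSC_ctrl
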