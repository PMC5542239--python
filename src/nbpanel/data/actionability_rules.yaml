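# Drug-matching rules: a patient is a molecular target candidate when at
# least one rule fires on their retained somatic alterations.
rules:
  - gene: ALK
    trigger: protein_change
    changes: [R1275Q, F1174I, R1192G]
    therapy_class: ALK inhibitor
  - gene: ALK
    trigger: cn_gain
    therapy_class: ALK inhibitor
  - gene: BRCA1
    trigger: truncating
    therapy_class: PARP inhibitor
  - gene: ATM
    trigger: cn_loss
    therapy_class: PARP inhibitor
  - gene: HRAS
    trigger: protein_change
    changes: [Q61R]
    therapy_class: RAS pathway inhibitor
  - gene: MET
    trigger: exon_skip
    therapy_class: MET inhibitor
  - gene: ERBB2
    trigger: cn_gain
    therapy_class: HER2-targeted therapy
  - gene: STK11
    trigger: cn_loss
    therapy_class: mTOR inhibitor
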