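# Default marker panel for PBMC / T-lymphocyte cluster annotation.
# Rules are evaluated in order; the first rule whose "high" markers are all
# flagged high and "low" markers all flagged low labels the cluster.
# Clusters matching no rule are labelled "unidentified".  When ctla4_split
# is true, Treg clusters are further separated into CTLA4+ / CTLA4- states.
ctla4_split: true
rules:
  - label: Treg
    high: [CD4, FOXP3, IL2RA, TIGIT]
    low: []
  - label: Naive CD4 T
    high: [CD4, FHIT, CCR7]
    low: []
  - label: Helper T
    high: [CD4]
    low: [FHIT, CCR7]
  - label: Cytotoxic T
    high: [CD8A]
    low: []
  - label: NK cell
    high: [NKG7, GNLY]
    low: []
  - label: Non-classical monocyte
    high: [FCN1, CD14, FCGR3A]
    low: []
  - label: Classical monocyte
    high: [FCN1, CD14]
    low: [FCGR3A]
  - label: B cell
    high: [CD19, VPREB3]
    low: []
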