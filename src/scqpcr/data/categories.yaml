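# Functional category map for the 85-gene monocyte panel.
# A gene may belong to more than one category (e.g. CD93 appears under both
# adhesion/migration and phagocytosis).
antigen_presentation:
  - CD40
  - CD74
  - HLA-DRA
  - HLA-DRB1
adhesion_migration:
  - CD33
  - CD93
  - CCR1
  - CCR2
  - CCR5
  - CCR9
  - CX3CR1
  - ITGAE
  - ITGAL
  - ITGAM
  - ITGAX
  - SELL
  - SIGLEC10
differentiation_and_function:
  - BAX
  - BCL2
  - BCL2L1
  - CSF1R
  - IRF4
  - IRF5
  - IRF8
  - NFKB1
  - PTPRC
  - RARA
  - RELA
  - S100A4
scavenger_receptors:
  - CD36
  - CD68
  - CD163
  - MARCO
  - MSR1
phagocytosis_bacterial_clearance:
  - CD93
  - CD209
  - CLEC4E
innate_immune_responses:
  - ADAM17
  - C1QA
  - CD14
  - FCGR3A
  - HMOX1
  - LTB
  - MICA
  - MICB
  - RAET1E
  - RAET1G
  - RAET1L
  - SERPINB2
  - SIRPA
  - TLR2
  - TLR3
  - TLR4
  - TLR7
  - TLR8
  - TLR9
  - TNFSF15
  - TREM1
  - TREM2
  - ULBP3
cytokines:
  - IL10
  - IL12A
  - IL15
  - IL18
  - IL1B
  - IL23A
  - IL6
  - TNF
proteases_and_inhibitors:
  - CST3
  - CTSB
  - CTSK
  - CTSL
  - CTSS
  - MMP1
  - MMP2
  - MMP3
  - MMP7
  - MMP9
  - TIMP1
  - SERPINA1
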