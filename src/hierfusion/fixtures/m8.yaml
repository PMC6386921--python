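# Google-Glass 20-activity set, 8-state grouping: sedentary and standing kept
# apart. Activities doable either seated or standing (eating, drinking,
# texting, phone calls, reading, organizing files) belong to both groups, so
# this grouping is genuinely many-to-many (group sizes sum to 26 > 20).
activities:
  - WK
  - WK-US
  - WK-DS
  - RD-VU
  - RD-VD
  - RD-SU
  - RD-SD
  - SI
  - ET
  - DR
  - TX
  - MP
  - PC
  - RD
  - WT
  - OF
  - RN
  - DPU
  - DSU
  - CY
motion_states:
  - WK/WK-US
  - WK-DS
  - SD
  - ST
  - RN
  - DPU
  - DSU
  - CY
correspondence:
  WK/WK-US: [WK, WK-US]
  WK-DS: [WK-DS]
  SD: [SI, ET, DR, TX, MP, PC, RD, WT, OF]
  ST: [RD-VU, RD-VD, RD-SU, RD-SD, ET, DR, TX, MP, RD, OF]
  RN: [RN]
  DPU: [DPU]
  DSU: [DSU]
  CY: [CY]
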