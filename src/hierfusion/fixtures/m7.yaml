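# Google-Glass 20-activity set, 7-state grouping: cycling split out of the
# low-motion group as its own singleton state.
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
  - SD/ST
  - RN
  - DPU
  - DSU
  - CY
correspondence:
  WK/WK-US: [WK, WK-US]
  WK-DS: [WK-DS]
  SD/ST: [RD-VU, RD-VD, RD-SU, RD-SD, SI, ET, DR, TX, MP, PC, RD, WT, OF]
  RN: [RN]
  DPU: [DPU]
  DSU: [DSU]
  CY: [CY]
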