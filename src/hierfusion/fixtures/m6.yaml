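# Google-Glass 20-activity set, 6-state grouping: the grouping adopted for
# headline evaluation. Walking downstairs separates cleanly from level/upstairs
# walking; the four exercise-style states are singletons resolved by the
# motion sensor alone.
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
  - SD/ST/CY
  - RN
  - DPU
  - DSU
correspondence:
  WK/WK-US: [WK, WK-US]
  WK-DS: [WK-DS]
  SD/ST/CY: [RD-VU, RD-VD, RD-SU, RD-SD, SI, ET, DR, TX, MP, PC, RD, WT, OF, CY]
  RN: [RN]
  DPU: [DPU]
  DSU: [DSU]
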