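# Google-Glass 20-activity set, coarse 5-state grouping: all walking styles
# merged into one ambulatory state, all low-motion activities (including
# cycling, which is hard to tell apart from sitting at the waist) into one.
activities:
  - WK      # walking
  - WK-US   # walking upstairs
  - WK-DS   # walking downstairs
  - RD-VU   # riding elevator up
  - RD-VD   # riding elevator down
  - RD-SU   # riding escalator up
  - RD-SD   # riding escalator down
  - SI      # sitting
  - ET      # eating
  - DR      # drinking
  - TX      # texting
  - MP      # making phone calls
  - PC      # working at PC
  - RD      # reading
  - WT      # writing sentences
  - OF      # organizing files
  - RN      # running
  - DPU     # doing push-ups
  - DSU     # doing sit-ups
  - CY      # cycling
motion_states:
  - WK/WK-US/WK-DS
  - SD/ST/CY
  - RN
  - DPU
  - DSU
correspondence:
  WK/WK-US/WK-DS: [WK, WK-US, WK-DS]
  SD/ST/CY: [RD-VU, RD-VD, RD-SU, RD-SD, SI, ET, DR, TX, MP, PC, RD, WT, OF, CY]
  RN: [RN]
  DPU: [DPU]
  DSU: [DSU]
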