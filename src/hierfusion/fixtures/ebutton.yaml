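# eButton chest-worn life-logger hierarchy: 15 activities of daily living,
# 4 motion states. Multi-state activities (e.g. telephone use) appear in
# every group they can occur in, so group sizes sum to 24 > 15.
activities:
  - CU   # computer use
  - ET   # eating
  - EM   # entertainment
  - MT   # meeting
  - NP   # nap
  - RD   # reading
  - SP   # shopping
  - SW   # sweeping
  - TK   # talking
  - TU   # telephone use
  - TP   # transportation
  - WO   # walking outside
  - WU   # washing up
  - TV   # watching TV
  - WT   # writing
motion_states:
  - LY   # lying
  - SD   # sedentary
  - ST   # standing
  - WK   # walking
correspondence:
  LY: [NP, TU]
  SD: [CU, ET, EM, MT, RD, SP, TK, TU, TP, TV, WT]
  ST: [ET, EM, RD, SP, SW, TK, TU, TP, WU]
  WK: [SP, WO]
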