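# BIS-11 scoring key: 30 items rated 1-4; reverse-scored items are scored
# 5 - response; the six first-order subscales partition the 30 items and
# their sums add up to the total score (30-120).
reversed_items: [1, 7, 8, 9, 10, 12, 13, 15, 20, 29, 30]
subscales:
  attentional: [5, 9, 11, 20, 28]
  cognitive_instability: [6, 24, 26]
  motor: [2, 3, 4, 17, 19, 22, 25]
  perseverance: [16, 21, 23, 30]
  self_control: [1, 7, 8, 12, 13, 14]
  cognitive_complexity: [10, 15, 18, 27, 29]
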