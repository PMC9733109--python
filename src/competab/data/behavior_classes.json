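{
  "offensive": ["attack", "chase", "fight", "bite", "box", "tail_rattle"],
  "defensive": ["flight", "escape_to_water", "submissive_posture"],
  "neutral": ["cleaning", "sniffing", "vocalization"]
}
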