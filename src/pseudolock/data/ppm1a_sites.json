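{
  "reference_id": "PPM1A",
  "comment": "Approximate transcription of the PPM1A metal-coordination constellation (M1/M2/M3) from the structural literature; replace with your own numbering for production use.",
  "sites": [
    {"role": "M1", "position": 37, "allowed": ["E", "D"], "required": false},
    {"role": "M1", "position": 38, "allowed": ["D"], "required": true},
    {"role": "M2", "position": 60, "allowed": ["D"], "required": true},
    {"role": "M3", "position": 146, "allowed": ["D"], "required": false},
    {"role": "M2", "position": 239, "allowed": ["D"], "required": true},
    {"role": "M2", "position": 282, "allowed": ["D"], "required": true}
  ]
}
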