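{
  "class_names": ["CGE", "dMGE", "vMGE"],
  "class_counts": [856, 957, 856],
  "total_transcripts": 37310,
  "all_zero_transcripts": 6037
}
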