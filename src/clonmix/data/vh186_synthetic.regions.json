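{
  "name": "VH186.2-synthetic",
  "reading_frame_offset": 0,
  "regions": [
    [
      "FR1",
      1,
      75
    ],
    [
      "CDR1",
      76,
      105
    ],
    [
      "FR2",
      106,
      147
    ],
    [
      "CDR2",
      148,
      171
    ],
    [
      "FR3",
      172,
      294
    ]
  ],
  "note": "synthetic reference: engineered to satisfy VH186.2 coordinate conventions, not a database allele"
}
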