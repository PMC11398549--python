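{
  "classes": [
    [
      "BA_L",
      "SMA"
    ],
    [
      "PreMA_L",
      "PreMA_R"
    ],
    [
      "BA_R",
      "WA_L",
      "WA_R"
    ],
    [
      "SMG_L",
      "SMG_R"
    ],
    [
      "AG_L",
      "AG_R"
    ]
  ]
}
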