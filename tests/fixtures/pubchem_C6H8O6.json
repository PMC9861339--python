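{
  "PropertyTable": {
    "Properties": [
      {"CID": 54670067, "Title": "Ascorbic Acid"},
      {"CID": 440917, "Title": "D-Glucurono-6,3-lactone"},
      {"CID": 5460677, "Title": "Isoascorbic acid"}
    ]
  }
}
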