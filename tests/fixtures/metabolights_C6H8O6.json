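{
  "content": [
    {"id": "MTBLC38559", "name": "ascorbic acid"},
    {"id": "MTBLC27956", "name": "D-glucurono-1,4-lactone"}
  ]
}
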