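{
  "table1_edr.tsv": "52676f22c3917218e83ff4750b438a413588340a7ae288c9648b2538eaf4a59c",
  "table1_ked.tsv": "9764a2be325408e275cb6440d17079a3e6bd571d33ff27253aa00b58c90eca7e",
  "table2_occurrences.tsv": "a746c67acaaa952d5497f4ed85c9e5f4a87442b1d2bb2a2082722bf7e7585170"
}
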