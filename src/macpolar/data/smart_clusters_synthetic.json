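{
 "C13": [
  "C13_001",
  "C13_002",
  "C13_003",
  "C13_004",
  "C13_005",
  "C13_006",
  "C13_007",
  "C13_008",
  "C13_009",
  "C13_010",
  "C13_011",
  "C13_012",
  "C13_013",
  "C13_014",
  "C13_015",
  "C13_016",
  "C13_017",
  "C13_018",
  "C13_019",
  "C13_020"
 ],
 "C14": [
  "C14_001",
  "C14_002",
  "C14_003",
  "C14_004",
  "C14_005",
  "C14_006",
  "C14_007",
  "C14_008",
  "C14_009",
  "C14_010",
  "C14_011",
  "C14_012",
  "C14_013",
  "C14_014",
  "C14_015",
  "C14_016",
  "C14_017",
  "C14_018",
  "C14_019",
  "C14_020"
 ],
 "C3": [
  "C3_001",
  "C3_002",
  "C3_003",
  "C3_004",
  "C3_005",
  "C3_006",
  "C3_007",
  "C3_008",
  "C3_009",
  "C3_010",
  "C3_011",
  "C3_012",
  "C3_013",
  "C3_014",
  "C3_015",
  "C3_016",
  "C3_017",
  "C3_018",
  "C3_019",
  "C3_020"
 ]
}
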