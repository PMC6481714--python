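{
 "faces": [
  {"name": "NT_base", "segments": [[30, 36]]},
  {"name": "hydrophobic", "segments": [[37, 40], [54, 56], [69, 72], [87, 92]]},
  {"name": "alkaline", "segments": [[42, 45], [57, 60], [75, 78], [93, 95]]},
  {"name": "amphipathic", "segments": [[48, 51], [63, 66], [81, 83]]},
  {"name": "CT_base", "segments": [[96, 99]]}
 ],
 "stacked_pairs": [
  [43, 58, "exposed"],
  [58, 76, "exposed"],
  [48, 63, "buried"],
  [63, 81, "buried"],
  [50, 65, "buried"],
  [34, 51, "exposed"]
 ],
 "rungs": [[30, 47], [48, 62], [63, 80], [81, 99]]
}
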