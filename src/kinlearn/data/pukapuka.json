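{
  "language": "pukapuka",
  "entries": {
    "kainga": {"kintypes": ["z", "pgd", "ped"], "map": "difference(generation0(X),sameGender(X))"},
    "matua-tane": {"kintypes": ["f", "pb"], "map": "male(child(parent(parent(X))))"},
    "matua-wawine": {"kintypes": ["m", "pz"], "map": "female(child(parent(parent(X))))"},
    "taina": {"kintypes": ["b", "pgs", "pes"], "map": "intersection(generation0(X),sameGender(X))"},
    "tupuna-tane": {"kintypes": ["pf"], "map": "male(parent(parent(X)))"},
    "tupuna-wawine": {"kintypes": ["pm"], "map": "female(parent(parent(X)))"}
  },
  "gender_dependent": ["kainga", "taina"],
  "swap_pairs": [["kainga", "taina"]]
}
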