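{
  "language": "english",
  "entries": {
    "aunt": {"kintypes": ["pz", "pgw"], "map": "female(difference(generation1(X),parent(X)))"},
    "brother": {"kintypes": ["b"], "map": "male(child(parent(X)))"},
    "cousin": {"kintypes": ["pgc", "pgec"], "map": "difference(generation0(X),child(parent(X)))"},
    "father": {"kintypes": ["f"], "map": "male(parent(X))"},
    "grandma": {"kintypes": ["pm"], "map": "female(parent(parent(X)))"},
    "grandpa": {"kintypes": ["pf"], "map": "male(parent(parent(X)))"},
    "mother": {"kintypes": ["m"], "map": "female(parent(X))"},
    "sister": {"kintypes": ["z"], "map": "female(child(parent(X)))"},
    "uncle": {"kintypes": ["pb", "pgh"], "map": "male(difference(generation1(X),parent(X)))"}
  },
  "gender_dependent": [],
  "swap_pairs": []
}
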