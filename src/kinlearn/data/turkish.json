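{
  "language": "turkish",
  "entries": {
    "abi": {"kintypes": ["b"], "map": "male(child(parent(X)))"},
    "abla": {"kintypes": ["z"], "map": "female(child(parent(X)))"},
    "amca": {"kintypes": ["fb"], "map": "intersection(sameGender(Fabio),difference(child(parent(male(parent(X)))),parent(X)))"},
    "anne": {"kintypes": ["m"], "map": "female(parent(X))"},
    "anneanne": {"kintypes": ["mm"], "map": "female(parent(female(parent(X))))"},
    "baba": {"kintypes": ["f"], "map": "male(parent(X))"},
    "babaanne": {"kintypes": ["fm"], "map": "female(parent(male(parent(X))))"},
    "dayi": {"kintypes": ["mb"], "map": "male(child(parent(female(parent(X)))))"},
    "dede": {"kintypes": ["pf"], "map": "male(parent(parent(X)))"},
    "eniste": {"kintypes": ["pgh"], "map": "intersection(lateral(child(parent(parent(X)))),male(complement(parent(X))))"},
    "hala": {"kintypes": ["fz"], "map": "female(child(parent(male(parent(X)))))"},
    "kuzen": {"kintypes": ["pgc", "pgec"], "map": "difference(generation0(X),child(parent(X)))"},
    "teyze": {"kintypes": ["mz"], "map": "difference(female(child(parent(female(parent(X))))),parent(X))"},
    "yenge": {"kintypes": ["pgw"], "map": "female(difference(generation1(X),parent(X)))"}
  },
  "gender_dependent": [],
  "swap_pairs": []
}
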