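{
  "language": "yanomamo",
  "entries": {
    "amiwa": {"kintypes": ["z", "fbd", "mzd"], "map": "female(child(coreside(X)))"},
    "eiwa": {"kintypes": ["b", "fbs", "mzs"], "map": "male(child(coreside(X)))"},
    "haya": {"kintypes": ["f", "fb"], "map": "male(coreside(X))"},
    "naya": {"kintypes": ["m", "mz"], "map": "female(coreside(X))"},
    "soaya": {"kintypes": ["mb"], "map": "male(difference(generation1(X),coreside(X)))"},
    "soriwa": {"kintypes": ["mbs", "fzs"], "map": "difference(male(generation0(X)),child(coreside(X)))"},
    "suaboya": {"kintypes": ["mbd", "fzd"], "map": "female(difference(generation0(X),child(coreside(X))))"},
    "yesiya": {"kintypes": ["fz"], "map": "difference(female(generation1(X)),coreside(X))"}
  },
  "gender_dependent": [],
  "swap_pairs": []
}
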