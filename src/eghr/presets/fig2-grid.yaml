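# Condition grid: all rules x (mixing, source family, temporal mode).
experiment: grid
rule: eghr
seed: 0
extra:
  rules: [eghr, amari, bell_sejnowski, cichocki]
  conditions:
    - {mixing: rotation, family: laplace, temporal: iid}
    - {mixing: non_rotation, family: uniform, temporal: iid}
    - {mixing: undercomplete, family: laplace, temporal: iid, N: 8}
  n_seeds: 2
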