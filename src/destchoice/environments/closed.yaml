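destinations:
- A
- B
- C
- D
- E
- F
distance_table:
  A:
    A: 0
    B: 5
    C: 3
    D: 7
    E: 6
    F: 8
    O: 3
  B:
    A: 5
    B: 0
    C: 4
    D: 6
    E: 3
    F: 7
    O: 4
  C:
    A: 3
    B: 4
    C: 0
    D: 5
    E: 4
    F: 6
    O: 6
  D:
    A: 7
    B: 6
    C: 5
    D: 0
    E: 4
    F: 3
    O: 8
  E:
    A: 6
    B: 3
    C: 4
    D: 4
    E: 0
    F: 5
    O: 7
  F:
    A: 8
    B: 7
    C: 6
    D: 3
    E: 5
    F: 0
    O: 9
  O:
    A: 3
    B: 4
    C: 6
    D: 8
    E: 7
    F: 9
    O: 0
name: closed
noise_mu: 0.0
noise_sigma: 1.4142135623730951
occupancy_table:
  1:
    A: 4
    B: 7
    C: 2
    D: 5
    E: 3
    F: 6
  2:
    A: 6
    B: 3
    C: 8
    D: 2
    E: 5
    F: 4
  3:
    A: 2
    B: 5
    C: 4
    D: 7
    E: 6
    F: 3
  4:
    A: 5
    B: 2
    C: 6
    D: 4
    E: 3
    F: 7
  5:
    A: 3
    B: 6
    C: 2
    D: 5
    E: 7
    F: 4
origin: O
time_budget: 60.0
trip_length: 5
w_d: 1.5
w_o: 1.0
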