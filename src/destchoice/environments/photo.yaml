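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
    B: 2
    C: 4
    D: 5
    E: 7
    F: 8
    O: 2
  B:
    A: 2
    B: 0
    C: 3
    D: 4
    E: 6
    F: 7
    O: 3
  C:
    A: 4
    B: 3
    C: 0
    D: 2
    E: 4
    F: 5
    O: 5
  D:
    A: 5
    B: 4
    C: 2
    D: 0
    E: 3
    F: 4
    O: 6
  E:
    A: 7
    B: 6
    C: 4
    D: 3
    E: 0
    F: 2
    O: 8
  F:
    A: 8
    B: 7
    C: 5
    D: 4
    E: 2
    F: 0
    O: 9
  O:
    A: 2
    B: 3
    C: 5
    D: 6
    E: 8
    F: 9
    O: 0
name: photo
noise_mu: 1.5
noise_sigma: 0.8660254037844386
occupancy_table:
  1:
    A: 6
    B: 3
    C: 8
    D: 4
    E: 5
    F: 2
  2:
    A: 6
    B: 3
    C: 8
    D: 4
    E: 5
    F: 2
  3:
    A: 6
    B: 3
    C: 8
    D: 4
    E: 5
    F: 2
  4:
    A: 6
    B: 3
    C: 8
    D: 4
    E: 5
    F: 2
  5:
    A: 6
    B: 3
    C: 8
    D: 4
    E: 5
    F: 2
origin: O
time_budget: 15.0
trip_length: 5
w_d: 0.25
w_o: 0.15
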