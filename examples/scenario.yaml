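# Example synthetic scenario: two regimes, four topics.
# Utilities are per regime and per topic; "fourier" entries take
# a0/a/b/tau, "polynomial" entries take coef = [c0, c1, ...].
topics: [unemployment, symptoms, news, porn]
span: 52
noise_sd: 2.0
seed: 0
round_to_int: true
coverage: 0.5
area: exampleland
start_date: "2019-05-05"
regimes:
  - start: 0
    utilities:
      unemployment: {kind: polynomial, coef: [-2.2]}
      symptoms: {kind: polynomial, coef: [-1.7]}
      news: {kind: fourier, a0: -0.7, a: [0.05], b: [0.0], tau: 51.0}
      porn: {kind: polynomial, coef: [-1.2]}
  - start: 44
    utilities:
      unemployment: {kind: polynomial, coef: [-15.4, 0.3]}
      symptoms: {kind: polynomial, coef: [2.7, -0.1]}
      news: {kind: polynomial, coef: [3.7, -0.1]}
      porn: {kind: polynomial, coef: [3.2, -0.1]}
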