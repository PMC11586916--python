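# Scenario 3: Gompertz/Gompertz/Weibull intensities (true max distance
# ~0.003/day at t=0), administrative censoring at day 90.  Heavier to run;
# B: 100 keeps a desk-scale smoke test feasible.
scenario: 3
n_pairs: [[200, 200], [500, 500]]
deltas: [0.0028, 0.005, 0.01]
censorings: ["administrative:90"]
N: 100
B: 100
alpha: 0.05
method: global
seed: 1
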