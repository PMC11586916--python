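# Scenario 1: distinct all-exponential models (true max distance 0.0006/day),
# exponential random censoring.  Delta = 0.0006 is the null margin (level),
# larger values probe power.  Full-scale reference uses N: 1000.
scenario: 1
n_pairs: [[200, 200], [300, 300], [500, 500]]
deltas: [0.0006, 0.001, 0.0015]
censorings: ["exponential:0.001", "exponential:0.01"]
N: 200
B: 250
alpha: 0.05
method: global
seed: 1
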