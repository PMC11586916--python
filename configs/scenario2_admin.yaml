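# Scenario 2: identical all-exponential models (max power setting),
# administrative censoring at day 90.  Run with method: iup for the
# per-transition comparator.
scenario: 2
n_pairs: [[200, 200], [500, 500]]
deltas: [0.001, 0.0015]
censorings: ["administrative:90"]
N: 200
B: 250
alpha: 0.05
method: global
seed: 1
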