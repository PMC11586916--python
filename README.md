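# crsim — similarity testing for parametric competing-risks models

`crsim` decides whether two competing-risks models — e.g. the 90-day
hospital-readmission pathways of two patient populations — can be declared
**similar** at controlled Type I error.  It is aimed at biostatisticians and
health-services researchers working with time-to-first-event data with
several mutually exclusive event types and modest event counts.

## The statistical problem

Each group ℓ = 1, 2 starts in state 0 and can move to one of k absorbing
states; the movement is governed by parametric cause-specific transition
intensities α₀ⱼ⁽ℓ⁾(t, θ₀ⱼ⁽ℓ⁾) (exponential, Gompertz or Weibull, mixed
freely across transitions), observed with right censoring on a window
[0, τ].  Discrepancy is measured by the maximum sup-norm distance

    d = max_j  sup_{t ∈ [0,τ]} | α₀ⱼ⁽¹⁾(t) − α₀ⱼ⁽²⁾(t) |,

and the hypotheses are the equivalence pair

    H₀: d ≥ Δ        versus        H₁: d < Δ,

so that *rejecting H₀ certifies similarity* up to the prespecified margin Δ.
The test statistic is the plug-in distance d̂ of the group-wise maximum
likelihood fits.  Its reference distribution is obtained by a **constrained
parametric bootstrap**: the two models are re-estimated under the boundary
constraint d = Δ (whenever d̂ < Δ), B two-group datasets are regenerated
from these null models — with censoring regenerated from the fitted
censoring distribution, or truncated at τ for administrative censoring —
and H₀ is rejected when the bootstrap p-value F̂_B(d̂) = mean(d̂* ≤ d̂)
falls below α.  A per-transition variant combined by the intersection-union
principle, and a data-driven scan for the smallest rejecting Δ, are also
provided.

## Worked example

```python
import numpy as np
from crsim import (CensoringModel, generate_scenario_dataset,
                   scenario_spec, similarity_test)

censoring = CensoringModel.exponential(0.001)     # random censoring, rate/day
spec = scenario_spec(1, n1=300, n2=300, censoring=censoring)
ds = generate_scenario_dataset(spec, np.random.default_rng(2024))

res = similarity_test(ds.group(1), ds.group(2),
                      families=["exponential"] * 3,
                      delta=0.0015, B=250, alpha=0.05,
                      censoring=censoring, rng=np.random.default_rng(1))
print(res.d_hat, res.p_value, res.reject)
```

Running `python examples/similarity_test_basic.py` (which is this example
with a summary) prints:

```
observed statistic d-hat = 0.00053 per day (largest intensity difference across the three transitions)
bootstrap p-value        = 0.000  (B = 250)
5% bootstrap quantile    = 0.00111
decision at alpha = 0.05 : SIMILAR (reject H0)
```

The fitted intensities never differ by more than 0.00053 events/day across
the three transitions; since that observed maximum is far below the margin
Δ = 0.0015 relative to the bootstrap spread, the two pathways are declared
similar.  The other scripts in `examples/` each demonstrate one capability
(minimal-Δ scan, global vs per-transition testing, operating
characteristics, Gompertz/Weibull fitting).

## Command line

A thin CLI wraps the library:

```bash
crsim simulate --scenario scenario1 --n1 200 --n2 200 --seed 7 --out d.csv
crsim test --data d.csv --families exp,exp,exp --delta 0.0015 \
           --censoring administrative:90 --seed 1
crsim minimal-delta --data d.csv --families exp,exp,exp --delta-grid 0:0.01:0.0001
crsim study --config configs/scenario1_random_censoring.yaml --out results.csv
```

Datasets are plain CSV (`id,time,status,group`; status 0 = censored, times
in days); results are JSON.

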