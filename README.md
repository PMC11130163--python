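# spineclust

Analytics for longitudinal two-photon imaging of synaptic remodeling:
dendritic spines tracked across imaging sessions on linear branchlets, and
presynaptic boutons tracked along axons — the kind of data produced when the
same cortical dendrites and axons are re-imaged every few days in vivo.

The package answers the questions such studies ask:

- **Turnover** — what fraction of spines is generated or eliminated per
  interval, per dendrite and pooled?
- **Clustering bias** — do newly generated spines appear closer together
  than a uniform random placement predicts? This is the package's core
  inference, a Monte Carlo permutation test on 1-D point positions.
- **Fates, carryover and survival** — of the spines born between the first
  two sessions, how many persist to the third (*carryover* spines), and how
  does their survival compare to pre-existing spines?
- **Bouton dynamics** — detection of presynaptic varicosities from axial
  intensity profiles (≥2× flanking-backbone rule), 1-µm identity matching
  across sessions, and generation/elimination rates stratified by
  projection (local/ipsilateral vs callosal/contralateral axons).
- **Cross-species concordance** — for paired differential-expression tables
  (animal model vs control, human case vs control), the per-module
  percentage of genes changing in the same direction, with a one-sided
  binomial test against the 50% chance level.

A seeded synthetic-data module generates spine datasets, axon intensity
profiles, small fluorescence z-stacks and paired logFC tables with the
statistical structure the analyses assume, so the whole pipeline is
testable without imaging data.

## The clustering-bias test

Let each branchlet *i* have length *L<sub>i</sub>* and carry the positions
of the spines generated (or eliminated) over one interval. Branchlets are
concatenated end-to-end in random order into one pseudo-dendrite of length
*L* = Σ*L<sub>i</sub>*, and the observed statistic is the *clustering
probability*

> c(d) = (# consecutive-neighbour gaps ≤ d) / (n − 1),

averaged over 1000 random concatenation orders (default threshold d = 3 µm).
The null model redraws the n event positions i.i.d. uniform on [0, L]
(100,000 iterations by default) and the empirical P-value is the fraction
of iterations whose null clustering probability is at least the observed
value. A per-dendrite mode keeps each branchlet's own event count and
redraws positions within that branchlet instead. For n uniform points the
null mean has the closed form E[c(d)] = 1 − (1 − d/L)<sup>n</sup>, which the
test suite uses as an independent oracle. A threshold sweep (3/6/9 µm)
reports the cut-off with the largest observed-minus-chance margin
(Youden-style optimal separation).

## Worked example

```python
import dataclasses
from spineclust.synthetic_data import VPA_PRESET, generate_spine_dataset
from spineclust.spine_dynamics import generation_rate, elimination_rate
from spineclust.cluster_null import events_from_dataset, monte_carlo_null

cfg = dataclasses.replace(VPA_PRESET, n_dendrites=12, cluster_bias=0.8, seed=11)
ds = generate_spine_dataset(cfg)          # 3 sessions, 3-day intervals
print(round(generation_rate(ds, (0, 1)).pooled_pct, 1))
print(round(elimination_rate(ds, (0, 1)).pooled_pct, 1))

events = events_from_dataset(ds, (0, 1), "generated")
res = monte_carlo_null(events, threshold_um=3.0, iterations=100_000, seed=42)
print(round(res.observed_prob, 3), round(res.null_p95, 3), res.empirical_p)
```

prints

```
11.7
15.2
0.506 0.308 2e-05
```

— a 3-day generation rate of 11.7% and elimination rate of 15.2% (this
preset draws per-spine birth/death probabilities of 10.2%/12.5%; a single
12-dendrite realization scatters around them), and an observed clustering
probability of 0.506 that far exceeds the null 95th percentile (0.308),
with an empirical P of 2 × 10⁻⁵: the injected clustering bias is detected.
With `cluster_bias=0.0` the same pipeline returns P-values uniform on
[0, 1].

The same stages are scriptable from a shell:

```
spineclust simulate --preset VPA --cluster-bias 0.8 --seed 11 \
    --spines-out spines.csv --dendrites-out dendrites.csv
spineclust cluster --spines spines.csv --dendrites dendrites.csv \
    --threshold 3 --iterations 100000 --seed 42 --out result.json
spineclust report --spines spines.csv --dendrites dendrites.csv --seed 42
```

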