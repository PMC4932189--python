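# mdeflux

Quantifying biotic interchange through time from dated phylogenies.

When two long-separated biotas come into contact — the textbook case being
the Eocene collision of the Indian subcontinent with mainland Asia — the
flux of lineages across the new contact zone is not directly observable.
What *is* observable is a collection of range-shift events scattered across
many independently dated phylogenies, each event carrying a 95% highest
posterior density (HPD) interval for the divergence time of the node where
ancestral-area reconstruction infers the move.

`mdeflux` turns such a compilation into a time series and asks when the
dispersal regime changed:

1. **MDE series.** For every 1-Myr time slice *t* on a 0–70 Ma grid, the
   MDE (maximal number of observed dispersal events per Myr) is the count
   of events whose HPD interval, rounded to the nearest full million years,
   covers *t*:

   MDE(t) = Σ_i 1{ yᵢ ≤ t ≤ oᵢ },

   where (yᵢ, oᵢ) are the rounded young/old bounds of event *i*. Summing
   interval coverage, rather than point estimates, treats co-occurring
   intervals as evidence of concerted (geo-)dispersal and propagates dating
   uncertainty instead of hiding it.
2. **Smoothing and bias truncation.** A centred 5-Myr sliding mean removes
   slice-level noise. Because recent splits are systematically
   under-sampled except in densely sampled bird phylogenies, the series is
   truncated below the age where the smoothed avian and non-avian MDE
   trajectories intersect.
3. **Change-point analysis.** Shifts in the MDE regime are located with a
   from-scratch e-divisive algorithm: hierarchical bisection under the
   empirical energy divergence of Székely and Rizzo,

   ê(X, Y; α) = 2/(nm) Σᵢⱼ |xᵢ−yⱼ|^α − C(n,2)⁻¹ Σᵢ<ₖ |xᵢ−xₖ|^α − C(m,2)⁻¹ Σⱼ<ₗ |yⱼ−yₗ|^α,

   maximising Q̂ = nm/(n+m) · ê over split positions and assessing each
   split by within-segment permutation (defaults: 500 permutations,
   significance 0.05, ≥5 observations between change points, α = 1).

Because absolute MDE values are inflated toward the present (the "pull to
the present" of reconstructed phylogenies), the scientific signal is in the
*shifts*, not the levels.

The package is for phylogeographers and biogeographers running
interchange meta-analyses: it consumes a plain TSV of events (one row per
inferred range shift with direction, taxon group and HPD bounds), not
trees — divergence dating and ancestral-area estimation happen upstream.

## Worked example

Simulate a known dispersal history — intensity 0.2 events/Myr from 70 to
30 Ma stepping to 2.0 events/Myr at 30 Ma, with HPD half-widths growing
with node age — and ask the change-point model to find the step:

```python
from mdeflux import (EDivisive, TimeGrid, compute_mde,
                     simulate_events, step_spec)

spec = step_spec(t_change=30.0, rate_old=0.2, rate_young=2.0, seed=42)
table = simulate_events(spec)          # 73 events
raw = compute_mde(table, TimeGrid(70))
res = EDivisive(raw).fit(n_permutations=500, seed=42)
print(res.summary())
```

```
E-Divisive Change-Point Results
=======================================================
Series label:      pooled
Observations:      71
Permutations (R):  500
Significance:      0.05
Min segment size:  5
Moment index:      1.0
Change points:     3
-------------------------------------------------------
order  index   age_ma      Q_hat        p
    3     11     59.0    24.6329   0.0020
    1     40     30.0   250.7533   0.0020
    2     66      4.0    59.8452   0.0020
=======================================================
```

The dominant split (detection order 1, Q̂ ≈ 251) lands exactly at the true
30 Ma intensity step. The two weaker splits are edge regimes of the series
itself: near 60 Ma the sparse old-regime events stop overlapping, and below
~4 Ma interval clipping at the present thins coverage. Ages are reported as
the age of the first observation of the younger regime; p-values use the
add-one permutation estimator, so 0.002 = 1/501 is the smallest attainable
value at R = 500.

The same analysis as a shell pipeline:

```sh
mdeflux simulate --spec spec.yaml --out events.tsv --seed 42
mdeflux compute --events events.tsv --out series.tsv --by pooled
mdeflux changepoints --series series.tsv --permutations 500 --seed 42
mdeflux run --config config.yaml          # full stratified pipeline + plots
```

## Layout

- `src/mdeflux/events.py` — event-table schema, IO, filtering
- `src/mdeflux/mde.py` — time grid, MDE binning, smoothing, bias truncation
- `src/mdeflux/changepoint.py` — energy divergence, e-divisive, model/results API
- `src/mdeflux/synthetic.py` — piecewise-Poisson event simulator
- `src/mdeflux/pipeline.py`, `src/mdeflux/cli.py` — orchestration, plots, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
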