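# Methods

## The MDE statistic

The unit of observation is a dispersal event: a node in a time-calibrated
phylogeny at which ancestral-area reconstruction infers a range shift
between two biotas, together with the 95% HPD interval of that node's
divergence time. The MDE (maximal number of observed dispersal events per
Myr) at integer age *t* is the number of events whose rounded HPD interval
covers *t*. It is an upper envelope, not an event count: an event
contributes to every slice its interval covers, so wide intervals spread
mass and co-occurring intervals stack. The statistic deliberately measures
*observed, potential* dispersal concentration given dating uncertainty;
extinction and incomplete sampling mean it cannot be read as an absolute
dispersal rate, which is why inference focuses on shifts in the series
rather than its level.

Assumptions inherited by everything downstream:

- events are exchangeable, independent contributions, even when several
  come from one source phylogeny (no within-dataset down-weighting);
- the HPD interval is an honest summary of dating uncertainty, so interval
  overlap between events is meaningful;
- a 1-Myr slice is fine enough to resolve the dynamics of interest.

### Binning conventions

The analysis grid is `t = 0 .. t_max` (default 70 Ma) in 1-Myr slices.
Interval bounds are rounded to the nearest full million years with the
half-away-from-zero tie rule (2.5 → 3); rounding is monotone, so young ≤
old is preserved. Coverage is inclusive on both ends, so a point interval
(young = old) covers exactly one slice and the total mass identity
Σ_t MDE(t) = Σ_events (o − y + 1) holds exactly after clipping. Events
whose rounded interval lies entirely above `t_max` are excluded with a
warning; straddling intervals are clipped. Series are stored oldest-first,
the orientation in which change-point ages are reported.

## Smoothing and the avian recency-bias truncation

Smoothing is a centred moving mean with an odd window (default 5 Myr);
the window truncates at the series ends rather than padding, so a constant
series is a fixed point and no mass is invented at the boundaries. Even
windows are rejected because the centre slice would be undefined.

Recent phylogenetic splits escape sampling in most groups, but not in bird
phylogenies sampled to subspecies level, whose MDE therefore rises sharply
toward the present while every other group's falls. The truncation
compares the smoothed avian series against the smoothed pooled non-avian
series and removes all slices younger than their intersection — the
youngest age at which the sign of (avian − non-avian) changes. Two
degenerate cases are fixed by convention: if the avian series never
strictly exceeds the non-avian one there is nothing to truncate (cutoff
0), and exact-tie plateaus resolve to their youngest point. The cut, when
applied, is applied to *all* series entering change-point analysis, so
strata remain comparable.

## E-divisive change-point analysis

Distributional change between segments X (n points) and Y (m points) is
measured by the empirical energy divergence

    ê(X,Y;α) = 2/(nm)·Σᵢⱼ|xᵢ−yⱼ|^α − C(n,2)⁻¹·Σᵢ<ₖ|xᵢ−xₖ|^α − C(m,2)⁻¹·Σⱼ<ₗ|yⱼ−yₗ|^α

scaled to Q̂ = nm/(n+m)·ê. For 0 < α < 2, ê is zero in expectation iff the
two distributions coincide, so Q̂ behaves as a nonparametric two-sample
statistic sensitive to any distributional difference, not only mean
shifts. α defaults to 1 (the plain energy distance); α = 2 reduces to a
mean-difference statistic and is admitted but not default.

The divisive search bisects: among all current segments and all split
positions κ leaving at least `min_size` observations on each side, take
the split maximising Q̂ (ties → smallest κ, the oldest admissible
boundary). Its significance is assessed by permuting observations within
each current segment — never across accepted change points, which the test
conditions on — and recomputing the maximal best-split Q̂ over all segments
for each of R permutations. The split is accepted iff

    p = (1 + #{ q_r ≥ q_obs }) / (R + 1) ≤ sig_level,

and the recursion continues inside the two halves; the first
non-significant globally-best split stops the search. The add-one
estimator keeps p strictly positive at finite R, which is what makes the
test's size guarantee exact. Defaults follow the published analysis
settings: R = 500, sig_level = 0.05, min_size = 5, α = 1.

### Numerical choices

- All split scans work from the pairwise |xᵢ−xⱼ|^α matrix via 2-D
  cumulative sums, so scanning every admissible split of an n-point
  segment costs O(n²); permutations reuse the matrix by row/column
  reindexing. Results equal exhaustive search exactly (property-tested).
- Exceedance counting uses a 10⁻⁹ relative tolerance around q_obs.
  Count-valued series tie the observed statistic exactly under many
  permutations, and a strict float comparison drops such ties at random
  through summation-order noise, deflating p and inflating the false-
  positive rate. With the tolerance, the estimator tracks exhaustive
  permutation enumeration on tiny series and the empirical size of the
  full procedure on i.i.d. Poisson(3) null series of length 70 is 0.046
  (1000 replicates), below the nominal 0.05.
- One seeded generator is threaded through the whole recursion, with
  segments permuted in deterministic (left-to-right) order, so a run is
  bit-reproducible given (series, parameters, seed).
- Degenerate inputs: constant segments have Q̂ ≡ 0 everywhere and can
  never be significant (every permutation ties); series shorter than
  2·min_size are rejected outright.

### Raw or smoothed input

The pipeline defaults to analysing the smoothed series, matching the
published default, and exposes `changepoint_stage: raw` as the
alternative. The trade-off is real: smoothing suppresses slice-level
noise, but a moving mean induces autocorrelation that the permutation
null (which assumes within-segment exchangeability) does not model, so
p-values on smoothed series run anticonservative and secondary change
points should be read with that in mind — in practice the dominant split
(detection order 1) is the robust one. The size guarantee demonstrated by
the null-calibration check applies to raw, exchangeable series.

## Synthetic data generator

The generator produces event tables with the structure the method
assumes, so every stage is testable without any external compilation and
recovery can be benchmarked against known truth. Per (direction, taxon)
stratum, true event ages follow an inhomogeneous Poisson process with
piecewise-constant intensity λ(t) (events/Myr) tiling (0, t_max]; within a
regime the count is Poisson(λ·span) and ages are uniform. Each true age t
is dressed in a symmetric interval of half-width

    h(t) = (a + b·t) · exp(σ·Z),   Z ~ N(0,1),

clipped at the present (never re-drawn, mirroring real HPDs truncated at
0 Ma), so intervals always contain the true age and widen with node age —
the qualitative signature of Bayesian node dating. Defaults a = 1 Myr,
b = 0.1 (≈ 10% of age), σ = 0.2 give mid-series widths of a few Myr,
comparable to what re-dated phylogenies typically show at Cenozoic ages;
the benchmark step spec (0.2 → 2.0 events/Myr at 30 Ma) yields on the
order of 70 events over 70 Myr, the scale of a real compilation.

What the generator does *not* emulate: extinction and lineage sampling
(observed events are generated directly, so there is no pull-to-the-present
artefact unless encoded in λ), asymmetric HPDs, between-dataset
calibration error (events are independent given λ), or any claim that the
affine width model matches a particular empirical compilation. Passing
recovery benchmarks therefore demonstrates that the *pipeline* finds
intensity shifts under honest dating noise — not that any particular
empirical series is correctly segmented.

## Design choices that were genuinely open

- Slice coverage inclusive on both ends, and half-away-from-zero
  rounding: chosen to make the mass identity exact and deterministic;
  neither convention is dictated by the method's definition.
- Tie-breaking in the split search (smallest κ) and plateau resolution in
  the bias cut (youngest point): fixed for determinism.
- The bias cut is computed on smoothed series, consistent with comparing
  smoothed trends, and applied to every analysed stratum.
- Events older than the analysis span are dropped rather than aggregated
  into the oldest slice, since the span bounds the question being asked.

## Problem sizes

The validity and recovery checks are sized for a single CPU: 200 null
series and 100 recovery replicates at R = 500 permutations each, with the
O(n²) split scan keeping a full 70-point analysis under ~0.1 s. These
sizes put the Monte-Carlo standard error of a 0.05-level rate estimate at
~0.015, small enough to detect meaningful miscalibration.

## Known limitations

- MDE is an envelope statistic; levels are not dispersal rates, and the
  method only ever interprets shifts.
- The permutation null assumes within-segment exchangeability; serially
  dependent input (e.g. heavily smoothed series) breaks the nominal size.
- Change-point ages inherit the 1-Myr grid and the min_size spacing:
  nothing closer than `min_size` slices to a series end or to another
  change point is detectable.
- The hierarchical search is greedy; a masked change point (two opposing
  shifts inside one segment) can be missed if neither sub-split is
  individually significant.
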