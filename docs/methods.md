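# Methods

## Delivery model

The toolkit models a ring-gantry linac with a binary multi-leaf collimator
(MLC). Delivery is discretised into *firing events*: the gantry rotates
continuously at `gantry_rpm` (default 60 RPM) and may pulse the beam at
`fp_per_rotation` evenly spaced firing positions per rotation (default 50,
hence a 7.2° sector and 50 aperture updates per second). The treatment
couch is stationary during beam-on and steps `couch_step_mm` (default
2.1 mm) between segments, monotonically in one direction (one-pass plans;
non-monotonic couch sequences are rejected as invalid rather than
re-keyed). Each firing event carries a binary leaf mask of `n_leaves`
(default 64) open/closed states and an MU value that is either zero or the
machine-wide quantum

```
MU_fp = nominal_dose_rate / (gantry_rpm × fp_per_rotation)   # 1/3 MU by default
```

The quantum is treated as a machine-level constant, not a plan-level one:
plan-MU / firing-position ratios implied by representative clinical
extremes (3184/9566, 7259/21 817) agree with it to <0.1%, and a single
constant is what makes the MU-vs-skips relationship exactly proportional.

Angle convention: IEC-style degrees in [0, 360), 0° at vertical top,
increasing in the rotation direction. Whether the start angle is fixed or
varies per rotation is not assumed: files store each event's gantry angle
explicitly, and validation anchors the 7.2° grid per rotation at that
rotation's first observed event.

## Comparison semantics

All analysis discards zero-MU firing events first (they carry no dose;
logs retain them because the leaves still move through them). Matching
between plan and delivery is by the exact integer key
`(couch_index, rotation_index, firing_index)` — the machine fires on fixed
grids, so float-tolerance matching on couch/gantry coordinates is
unnecessary once a sequence passes structural validation.

* A planned nonzero-MU key absent from the delivery is a **skip**. Skips
  are designed fault mitigation, so the CLI treats them as exit-0 results.
* A delivered nonzero-MU event with no planned counterpart
  ("unplanned"), a differing leaf mask ("mask-mismatch"), or an MU that is
  neither 0 nor `MU_fp` within 1e-6 MU ("mu-anomaly") is a **misfire**
  and raises the CLI's QA-flag exit code 3. A matched event with a wrong
  mask is a misfire, not a skip — skips are strictly *missing* events.
* MU reconciliation counts events: plan total = planned nonzero events ×
  `MU_fp`; delivered total counts only delivered events with a plan
  counterpart. Consequently `mu_reduction = n_skipped × MU_fp` and
  `percent_reduction = percent_skipped` hold to floating-point precision —
  the mechanism behind the R² = 1.000 cohort fit.

## Leaf transition rates

Between consecutive events within one couch segment the number of leaf
state changes is the Hamming distance of the masks. Intervals never span a
couch shift (beam off, couch moving), so each segment is an independent
stream. Zero-MU events contribute their masks and dwell time here — beam-on
time exceeds the nonzero-event count divided by the firing frequency in
clinical courses, implying zero-MU positions occupy real machine time —
but never contribute to the open-count aggregation matrices.

* `avg_rate` = total changes / beam-on seconds, with beam-on seconds =
  total events / firing frequency. Note the denominator counts events, not
  intervals, so a fully saturated toggler approaches but does not reach the
  physical bound `n_leaves × frequency` = 3200 leaves/s (an n-event segment
  attains 3200·(n−1)/n).
* `max_rate` = peak over sliding windows of `window_intervals` consecutive
  intervals of (window change sum)/(window duration). The default window is
  one rotation (50 intervals = 1 s at the default machine): clinically
  reported maxima are not multiples of the per-interval granularity × 50 Hz,
  so an instantaneous definition cannot be what is meant; the window length
  is a declared choice, configurable down to `window_intervals=1` for the
  instantaneous variant. A segment shorter than the window contributes its
  total change count against the full window duration (a conservative
  convention; consequently `avg_rate ≤ max_rate` is only guaranteed when
  segments are at least one window long, which holds for all generator
  defaults).

## Aggregation matrices

For each nonzero-MU event, each open leaf increments `leaf_by_couch[leaf,
couch]` and `leaf_by_gantry[leaf, firing]`, and `couch_by_gantry[couch,
firing]` increments by one. Gantry binning is by firing index (50 bins),
not raw angle, so plan-minus-delivery differences are bin-exact: for
skip-only deliveries every difference entry is a non-negative integer, the
couch×gantry difference sums to the skip count, and the leaf marginals sum
to the open-leaf count of the skipped events.

## Synthetic data: what it emulates and what it does not

The generator (`beamletqa.synth`) emulates the *structure* of clinical
one-pass courses; vendor logs are proprietary, so defaults are declared
study conditions rather than fitted estimates:

| parameter | default | rationale |
|---|---|---|
| `ptv_length_mm_range` | (43, 200) mm | clinical target-length range |
| `couch_margin_steps` | 3 | brings couch-position counts to the reported 27–103 range |
| `rotations_per_couch_range` | (5, 9) | ~7 rotations/couch reproduces ~16 000 nonzero positions and ~480 s beam-on per fraction |
| `zero_mu_fraction` | 0.3 | gap between beam-on time and nonzero-position count implies ~30% zero-MU positions |
| `skip_prob` | 0.0019 | calibrated to the reported 0.19% mean skip rate |
| `misfire_prob` | 0 | clinical analyses detect none; nonzero only for detector tests |
| `fractions_range` | (5, 33) | clinical fraction-count range |

Skips are independent Bernoulli draws per nonzero-MU position: observed
skip rates show no strong correlation with modulation (transient faults
strike at random w.r.t. the plan), and no burst/correlated fault model is
attempted. Randomness is split into per-patient and per-(patient,
fraction) substreams derived from one seed, so any item regenerates
identically in isolation.

Known non-emulated features — hence what passing tests do *not* show about
real data:

* Apertures are a single contiguous open run per event
  (`random-contiguous` redraws it each event; `sweep` drifts it one leaf
  per firing; `static` freezes it). No dose objective shapes them, and the
  default model over-modulates: its transition rates (~1250 leaves/s
  average) are ~20× clinical plans (35–86 leaves/s). Metrics are exercised
  across their range, but rate *magnitudes* are not clinically calibrated.
* Rotations per couch position are complete and uniformly drawn; real
  plans vary rotation counts with target shape and allow no partial
  rotations either, but their distribution is unpublished.
* Interlock behaviour (persistent faults halting delivery) and
  couch-direction-reversing plans are out of scope.

## File dialect and numerical conventions

BLSQ files are UTF-8 CSV with `#key=value` headers, `\n` line endings and
`.` decimals; leaf masks are exact `n_leaves`-character 0/1 strings (leaf 0
first). Writers render couch/gantry to 6 decimals and MU to 9; round-trip
equality is exact for masks and integers and within write precision for
floats (couch multiples of 2.1 mm are not exactly representable in binary
floating point, so bit-exactness is deliberately not promised). Validation
defaults: couch grid tolerance 0.1 mm, gantry grid tolerance 0.5°, MU
quantisation tolerance 1e-6 MU. Zero-MU events validate as warnings, never
errors.

Statistics: sample standard deviation uses the n−1 denominator (reported
as 0 with a logged warning for n = 1). Ordinary least squares and Pearson
correlations come from scipy (`linregress`/`pearsonr`); the test suite
cross-checks them against closed-form normal equations. Display rounding —
percentages 2 d.p., MU/rates/count-means 1 d.p. — is applied only in
presentation layers (text table, JSON report); stored values are unrounded.

## Problem sizes used in automated checks

The test suite and the acceptance script use scaled simulations chosen as
the package's own verification conditions: structural and oracle tests run
on compact plans (≈1.5–10 k events); the skip-rate recovery check pools
≥10⁵ Bernoulli trials per probability; the cohort-proportionality check
simulates 10 patients with 5–20 fractions and plans spanning roughly
9 000–22 000 nonzero firing positions. The proportionality result
(R² = 1.000) is seed-independent by construction; stochastic checks use
3-standard-error binomial bounds.
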