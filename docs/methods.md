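# Methods

## Scope and data model

The pipeline starts from a transcript x timepoint FPKM matrix whose first
column (t = 0, minutes) is the pre-starvation reference, plus three optional
side inputs: a module membership table (module id -> transcript ids, produced
upstream by a biclustering tool and taken as given), a transcriptional-
regulator (TR) annotation list, and a stoichiometric metabolic model with
gene-protein-reaction (GPR) rules. Four stages run in order — filtering,
wave ordering, influence inference, knockdown screening — each skippable when
its inputs are absent.

## Filtering

Log2 ratios use a +1 pseudocount on the FPKM scale, `r = log2((x+1)/(x0+1))`,
which keeps ratios finite when expression collapses to zero and pins the
reference column at exactly 0. Two retention rules follow:

- **Rule 1** — |r| > `fold_threshold` (default 1.0 log2 units, strict) at the
  lipid-accumulation timepoints (default 480, 720, 1440, 2880 min). The
  default demands the threshold at *all* four timepoints
  (`lipid_rule_mode=all`); `any` is available since the rule's phrasing admits
  that reading. Sign consistency across the four is *not* required but is recorded
  in the report.
- **Rule 2** — |r| > threshold with constant sign over a run of consecutive
  sampled timepoints spanning at least `min_period` (default 30) minutes,
  span measured last-minus-first. A single isolated sample never qualifies,
  however extreme.

Rule evaluation operates on sampled values only (no interpolation), so
refining the sampling grid can only preserve a qualifying run.

## Smoothing

All temporal logic runs on dense 1-min-step profiles obtained from a cubic
smoothing spline (scipy's `make_smoothing_spline`). The penalty `lam` defaults
to the routine's generalized-cross-validation choice, recorded in the profile
metadata; `lam=0` gives exact interpolation (used by several tests to isolate
other numerics). The 1-min grid matches the minute-resolution timestamps the
wave stage reports.

## Waves

A module's profile is the unweighted mean of member log-ratios at the sampled
times, smoothed as above. Classification: `flat` if |r| never exceeds the
threshold (reported but excluded from waves); otherwise the direction is the
sign at first crossing, and the class is `transient` if the profile is back
inside the threshold at the final grid point, else `monotonic`. The timestamp
is the earliest grid time with |r| above threshold, linearly refined between
grid points. Modules sharing (class, direction, timestamp quantized to the
sampled timepoint at or before the crossing) merge into one wave; the wave's
reported timestamp and mean profile are recomputed over the union of member
transcripts. If averaging across modules dilutes the crossing below threshold,
the wave falls back to its earliest member timestamp rather than losing its
schedule. Stages use closed upper bounds — early [0, 18] min, mid (18, 60]
min, late beyond — with everything after 60 min labeled late, including
timestamps past the nominal 8-h window.

## Regulator influences

Order of operations is smooth, then max-normalize (divide by the maximum
absolute value; identically-zero profiles are rejected as unscorable). For a
candidate lag L the distance between TR profile f and module profile g is the
RMS difference between f(t) and g(t+L) over the overlapping grid (RMS rather
than a plain sum so distances are comparable across lags with different
overlap lengths); the same comparison against −g captures repression, and the
pair's distance at L is the smaller of the two, with ties to activation. The
best lag minimizes this over 15–90 min at `lag_step` resolution (default
1 min; ties toward the smaller lag — the earliest plausible influence). The
edge threshold is the 5th percentile of the pooled per-pair best distances
(`pool=best`); pooling every (pair, lag) distance is available as `pool=all`.
TRs that fail the differential-regulation filter are excluded before scoring.

## Knockdown screen

`split_tag_from_biomass` removes the designated TAG species from the biomass
reaction (-> BM_TAG) and adds an exchange EX_TAG consuming them with their
original biomass coefficients. FBA maximizes a reaction flux subject to
`S v = 0` and bounds via scipy's HiGHS interface; because optimal flux
distributions are degenerate, a secondary parsimonious LP (minimize total
absolute flux at the optimum) fixes the wild-type distribution before
knockdown bounds are read, making the screen deterministic. A knockdown of
gene g caps every reaction whose GPR evaluates false without g (boolean mode;
`any-association` ignores isozyme rescue) at `|v_WT| / kd_factor` in the
wild-type direction, the reverse direction closed; reactions idle in the wild
type are pinned to zero (1/16 of zero is zero). Four LPs give
`rho = (TAG_pert/TAG_WT) / (BM_pert/BM_WT)`; viability demands
`BM_pert >= viability_fraction * BM_WT` and is applied as a post-hoc filter,
not as a constraint inside the TAG optimization (no biomass flux is enforced
during EX_TAG maximization). A gene touching no reaction leaves the model
unmodified and scores rho = 1 exactly by construction. `rho` is reported only
for viable perturbations; the raw biomass and TAG ratios are always reported.
The knockdown cap is implemented as an upper bound (<= v/16), the standard
knockdown semantics, not a fixed flux. Per-gene screening is primary;
screening a candidate list together simply shares the wild-type solves.

Precursor-gene search: for each precursor metabolite a temporary demand
reaction is added and maximized; flux variability at that optimum (demand
pinned) identifies every reaction able to carry nonzero flux toward the
demand, and the union of their GPR genes is returned. This procedure is the
package's own design choice for an otherwise unspecified step. The
cross-starvation classifier assigns each nitrogen-starvation target to
N-only / N+S / N+P / N+S+P by membership in supplied S- and P-starvation
downregulated gene sets.

GPR rules are parsed with a small recursive-descent parser (OR lowest
precedence, AND tighter, parentheses group) because locus identifiers such as
`Cre02.g082750` contain dots and are not valid Python identifiers. SBML
models are read through cobrapy and converted to the package's lightweight
structures; a documented JSON dialect covers the toy fixtures.

## Synthetic data

The generator emulates a 0–48 h starvation time course with dense early
sampling. Two grids are used, both declared emulations (the real experiment's
grid is not part of the package's inputs):

- the default 18-point grid (2-min steps to 12 min, then 18, 24, 30, 45, 60,
  120, 240, 480, 720, 1440, 2880 min) for filter and wave benchmarks;
- a regulator-benchmark grid with uniform 15-min sampling after the dense
  first 12 min, because lag identification is only meaningful at or above the
  sampling resolution.

Planted monotonic waves follow a baseline-anchored logistic
`r(t) = A (sigma(t) - sigma(0)) / (1 - sigma(0))` so that r(0) = 0 exactly
(as any ratio against the reference must be) while the plateau is exactly the
amplitude A (default 2 log2 units); transients are rescaled differences of
two logistics returning within |r| < 1 by 48 h. The logistic time constant
defaults to 8 % of the crossing time, clipped to [3, 30] min: transitions
unfold over tens of minutes, and the cap keeps late waves identifiable under
lag scanning. The internal crossing parameter is solved numerically (brentq)
so each planted curve crosses |r| = 1 exactly at its nominal timestamp, which
doubles as analytic ground truth.

Driver TR profiles equal their target wave's noiseless curve advanced by the
planted lag (negated for repression) and re-anchored to r(0) = 0; wave
crossings in the regulator benchmark sit at >= 250 min so the advanced curve
is numerically zero at t = 0 and the planted lag is exact. Decoy TRs carry
their own dynamics placed >= 250 min (in crossing time) away from any
same-shape wave, beyond reconciliation within the 15–90 min window. Noise is
Gaussian on the log-ratio scale — `x_t = (x0+1) 2^(r+eps) - 1`, clipped at
zero — the scale the thresholds operate on; baselines are log-normal
(median ~20 FPKM) floored at `2^(A_max+2)` so that a planted downregulation
can never clip at zero FPKM and distort the planted curve.

The regulator benchmark plants 10 TR -> wave influences with lags
{15, 30, 60, 90} min and mixed signs over 10 waves of 6 modules each
(8 transcripts per module, sigma = 0.1, 500 flat decoy transcripts): ground
truth is 60 TR -> module edges among 20 x 60 = 1,200 scored pairs — exactly
the 5 % the percentile threshold can emit, mirroring the multi-module reach
of real regulators. The benchmark scans lags at the 15-min sampling
resolution; at 1-min steps the distance valley is too flat for minute-level
lag claims under this noise (errors of a few minutes, occasionally a few tens
of minutes for the shallowest late waves).

Toy metabolic fixtures (chain / branch / isozyme) ship with hand-solved LP
outcomes: the branch knockdown that halves biomass while leaving TAG export
untouched (rho = 2 at kd_factor = 2), the chain knockdown that drops biomass
to 1/16 (inviable at the default 10 % rule), and the isozyme knockdown
rescued under boolean GPR semantics (rho = 1). kd_factor = 2 is used where an
outcome must remain viable to exercise the rho arithmetic; the default 16
inactivates these minimal single-path fixtures entirely.

**What passing benchmarks do not show.** The generator plants clean logistic
dynamics with homoscedastic log-ratio noise, modules whose members share one
curve, and regulators that are literal time-shifted copies of their targets.
Real data have replicate structure, heteroscedastic counts, partially
overlapping module membership, cooperative multi-TR regulation, and
regulator-target relationships far from pure time shifts — none of which the
recovery rates here speak to. The toy networks likewise exercise the rho
bookkeeping, not genome-scale degeneracy.

## Numerical choices

- LP tolerance 1e-9 on bound/viability comparisons; mass-balance checked to
  1e-6. Infeasible knockdown LPs score zero flux (an inviable perturbation),
  not an exception; unbounded models raise.
- Percentile thresholds use numpy's default linear interpolation; edges
  require distance strictly below the threshold, so `percentile=0` emits
  nothing.
- Crossing refinement is linear between adjacent grid values; a profile
  already beyond threshold at t = 0 is stamped 0.
- Lag scanning iterates ascending and keeps strict improvements, so ties
  resolve to the smallest lag deterministically.
- Output tables are written with `%.10g` floats and parameter-header comment
  lines; matrix TSVs round-trip bit-identically (round-trip float parsing on
  read). Manifests record SHA-256 hashes of every output.

## Limitations

- Module discovery (biclustering) is upstream and out of scope; modules are
  inputs.
- Influence inference is pairwise; cooperative multi-TR regulation of one
  module is not modeled, and unmatched regulators are simply absent from the
  edge list.
- The screen treats transcript abundance as a proxy for flux capacity through
  GPRs; protein-level effects, regulation, and thermodynamics are outside the
  model.
- The stage map hard-codes the early/mid/late boundaries of the nitrogen-
  starvation program; other stresses may need different boundaries.
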