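# Methods

## The generative model

A single mother-machine lineage is simulated: one cell grows
exponentially, `L(t) = L0 · exp(λt)`, undergoes replication-initiation
events (the origin count `n` doubles) and division events (length and
origin count halve, one daughter is followed). The central bookkeeping
quantity is the per-origin size `Λ(t) = L(t)/n`, which halves at every
initiation and is continuous across a symmetric division.

**Double adder.** At each initiation the recorded per-origin size is
`Λi = L/n_post` (post-duplication count). Two independent increments are
drawn:

* `dΛif` sets the next initiation threshold: initiation fires when
  `Λ(t)` reaches `Λi + dΛif`. Because the threshold is per origin it
  survives divisions unchanged.
* `dΛid` sets the matching division: a pending division target is
  queued at absolute length `Ld = n_post · (Λi + dΛid)`. Pending length
  targets are halved at every division, so targets set in a mother
  remain valid in her daughters under overlapping replication rounds.

At division the smallest pending target is retired, a division ratio
`r` is drawn around 0.5, a fair coin picks the followed daughter
(length `rL` or `(1−r)L`), and the daughter's growth rate is drawn from
a stationary AR(1) scheme with marginal mean `λ̄`, CV `λ_cv` and
mother-daughter correlation `ρ ≈ 0.3`.

**Competing variants** reuse the same machinery and differ in one
control rule each:

* `initiation_timer` — division fires a drawn *duration* after
  initiation (`dLid_mean` is then in minutes);
* `initiation_sizer` — initiation fires when `Λ(t)` reaches a freshly
  drawn critical size (`dLif_mean` is then that critical size, the
  classical initiation-mass picture);
* `independent_adders` — division is a classic birth-to-division
  length adder `dL` drawn at birth, uncoupled from replication
  (`dLid_mean` is then the mean `dL`). A division is deferred until the
  cell has at least two origins, since a cell cannot divide before
  having replicated; deferrals are counted as warnings.

All draws are truncated normals (values at or below 10% of the mean are
redrawn; the division ratio is restricted to (0.3, 0.7)); empirical
histograms can override any of them. More than 100 consecutive redraws,
or an origin count above 16 (runaway initiation), aborts the lineage
with a diagnostic.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `lambda_mean` | ln 2 / 89 | 1/min | 89-min doubling, glycerol-like slow growth |
| `lambda_cv` | 0.10 | — | typical single-cell growth-rate spread |
| `rho_lambda` | 0.3 | — | observed mother-daughter growth-rate correlation |
| `dLif_mean` | 1.0 | µm | per-origin inter-initiation increment |
| `dLid_mean` | 0.5 | µm | per-origin initiation-to-division increment; < `dLif` places initiation mid-cycle at slow growth |
| `dLif_cv`, `dLid_cv` | 0.17 | — | typical adder CVs; configurable, not condition-fixed |
| `ratio_sd` | 0.04 | — | division-placement noise around 0.5 |

The variant presets are chosen so all four models share the same
noise-free steady state (birth length 1.5 µm, one origin at birth): the
timer draws `ln(1.5)/λ̄ ≈ 52` min, the uncoupled adder draws
`dL = 1.5` µm, and the sizer draws a critical size of 2.0 µm. The
sizer's CV is set to 0.10, not 0.17: the adder chain produces an
initiation-size dispersion of `CV/√3 ≈ 0.10`, and the sizer — which
sets that size directly — should reproduce the same observable
dispersion, not the dispersion of the increments.

### Numerics

Growth between events is exact exponential algebra; when a threshold is
crossed inside a sampling step the event is applied at the exact
crossing (length set exactly to the threshold), in chronological order
within the step, initiation before division on ties. The sampling step
(default 1 min) therefore only controls the recorded trajectory grid,
and with all noise switched off the lineage converges to the analytic
fixed point of the per-origin map (`Λi* = dΛif`,
`Lb* = dΛif + dΛid` in the non-overlapping regime) to machine
precision; `deterministic_fixed_point` computes that state by exact
event iteration and flags limit cycles. Lineages are initialised as
newborns with one origin, a log-normal length around the fixed point
and mid-cycle counters; the first 10 generations are discarded as
burn-in (the system relaxes within a few generations). All randomness
derives from one integer seed (one spawned stream per lineage), so
equal seeds give bit-identical logs.

## Synthetic microscopy

The renderer emits the *output contract* of segmentation plus spot
detection, not images: frames every 3 min with multiplicative
log-normal length noise (CV 0.015), true origins placed at the
`(2i+1)/2n` fractional positions (origins sit at future division sites)
with 0.05-µm jitter, each origin detected with probability 0.98 per
frame (a live cell always shows at least one spot), and detected spots
closer than 0.25 µm fused — emulating the delayed apparent splitting
caused by origin cohesion. It does **not** emulate: point-spread
functions, segmentation errors correlated in time, cell crowding or
filamentation, or spot-intensity information. Passing tests on these
data therefore validate the pipeline's logic and its robustness to
frame sampling, length noise and imperfect spot counts — not its
behaviour under systematic imaging artefacts.

## Extraction

* **Division cycles.** Each cell's log-length is fit by OLS against
  time; `Lb`, `Ld` and `Li` are the fit evaluated at birth (first
  frame), division (daughter's first frame) and initiation, so
  measurement noise enters only through the fit and the identities
  `dL = Ld − Lb`, `Rbd = Ld/Lb`, `λ = log(Rbd)/Tbd` hold exactly on
  every record.
* **Initiation assignment.** The initiation frame is the first frame
  where the *persistent* spot count increases; a count is persistent
  once confirmed by the following frame, so single-frame blips are
  ignored. Persistent decreases, non-doubling jumps and
  parent/daughter count mismatches flag the cycle as incoherent.
* **Replication (pseudo-)cycles.** One record per pair of consecutive
  initiations, concatenating the mother segment (initiation→division)
  and the daughter segment (birth→initiation). `Λi` uses the
  post-duplication origin count and `Λf` the pre-duplication count —
  the only pairing that makes `dΛif = Λf − Λi` a positive per-origin
  adder — and consecutive records satisfy `Λf = 2·Λi(next)` exactly.
  Each segment's log per-origin size is fit separately and the growth
  rate `α` is the time-weighted mean of the two slopes. This is a
  deliberate choice: the per-origin series jumps by `2r` at division
  whenever the division ratio is noisy, and a single fit across the
  jump (or the pure identity `α = log(Rif)/Tif`) folds division noise
  into `α`, manufacturing a strong spurious `α`–`dΛib` correlation
  that would mask the independence structure the analysis is designed
  to measure. With the segment-wise fit, `α·Tif = log(Rif)` holds up to
  the division jump (exactly, under symmetric division).
* **QC.** Cycles with any incoherence flag are discarded, as are
  cycles whose fit residual SD exceeds 0.04 log units (both thresholds
  configurable); the report counts discards per reason. At the default
  observation noise this removes ~5% of division cycles and ~10–15% of
  pseudo-cycles, the same order as manual curation of real data
  discards.

## The decomposition framework

The division cycle alone carries 6 variables linked by 3 relations
(3 degrees of freedom); each full view carries 10 variables and 6
relations (4 degrees of freedom). Sufficiency of a candidate subset is
decided by constraint propagation: any relation with a single unknown
member is solved, iterated to a fixed point, on generic positive
numeric assignments (two independent random consistent points);
internally dependent subsets fail automatically because they cannot
reach the remaining variables. Note this is deliberately the
propagation notion of sufficiency — a subset like `{Rbd, Tbd, dL}`
whose completion requires solving two relations *simultaneously* is
classified insufficient.

For each sufficient subset the Pearson correlation matrix `R` is
computed on complete-case raw (untransformed) variables with two-sided
t-distribution p-values per pair, and the independence is `I = det(R)`,
clipped to [0, 1] (sample correlation matrices are PSD up to rounding;
by Hadamard's inequality the determinant cannot exceed 1). `I` is
invariant under positive affine rescaling of the variables. Sufficient
decompositions are ranked by `I` descending, ties broken
lexicographically; no multiple-testing correction is applied to the
ranking (the report footer says so). The replication- and
division-centric pools are ranked separately; mixed pools are not
enumerated.

## Diagnostics

Binned scatters use equal-count (quantile) bins — robust to skewed
size distributions — with bins under 5 points merged into a neighbour;
the count-weighted mean of bin means equals the global mean exactly.
The signed model contrasts report Pearson r, its p-value and a
pass/fail against the expected sign under a chosen generative model;
"no correlation" is operationalised as `|r| < 0.1` with `p > 0.01` at
the stated sample size.

## Problem sizes

The shipped tests and the acceptance script use 40–500 lineages of
30 h at 1-min steps (≈ 2 000–20 000 cycles after burn-in and QC),
sizes at which every headline statistic is stable to well within its
stated tolerance while the whole suite runs in a couple of minutes on
one CPU.

## Known limitations and honest findings

* **Division-cycle correlations of the threshold double adder.** With
  the per-origin threshold bookkeeping, event lengths are fully
  threshold-determined and the correlation structure is exactly
  derivable: `Λi` follows `Λi' = (Λi + dΛif)/2` and
  `Lb = 2r(Λi + dΛid)`. Hence the mother-daughter birth-length
  correlation is

      r_md = (σ_if²/6) / (σ_if²/3 + σ_id² + var(2r)·E[Lb]²)  ≈ 0.15

  at the default noise levels, and `corr(Lb, dL) ≈ −0.43` — the model
  reduces to the classic birth-to-division adder (r_md = 0.5, flat
  dL–Lb) only in the limit of vanishing division-adder and
  division-ratio noise, which the test suite asserts explicitly. The
  experimentally reported heritability of ≈ 0.5 is therefore *not*
  reproduced by this model at realistic division noise; this tension
  between the initiation-centric double adder and division-centric
  statistics is a real property of the model, not an implementation
  artefact (simulated and derived values agree to three decimals).
* **Measured division-adder spread.** The extracted `dΛib` includes
  division-placement noise (`var = σ_id² + var(2r)·E[Lb]²`), so its CV
  exceeds the drawn CV at nonzero `ratio_sd`; its mean is unbiased.
  Distribution-recovery checks for the CV are run at `ratio_sd = 0`.
* **Sizer null is only approximate.** Cycles whose initiation fell in
  the mother are excluded from the division-centric `Li` (inherited
  initiation), which truncates the critical-size draw at the birth
  size and leaves a small real `corr(Li, Lb) ≈ 0.08` under the sizer —
  far below the double adder's ≈ 0.35, but not exactly zero, so the
  compound "no correlation" gate is intrinsically marginal for this
  variant at large n.
* The renderer's spot model is minimal (no cohesion kinetics beyond a
  static merge radius, no tracking errors); the initiation-time proxy
  is biased late by up to one frame plus any merge delay.
* Replication-fork progression (C period), sister-cell statistics,
  whole-tree population structure and checkpoint-coupled concurrent
  models are out of scope.
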