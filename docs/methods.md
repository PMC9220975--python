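# Methods

## The alignment protocol

Valve events (MO, MC, AO, AC) are identified on echocardiogram timelines;
SCG/ECG beats are recorded separately. The protocol transfers the event
times onto arbitrary SCG beats in three stages.

**Reference selection.** Every candidate beat carries the RR interval of
its central cycle (from ECG R-peak detection). The reference is the beat
minimizing `|RR_beat − RR_echo|`; ties resolve to the earliest candidate.
The selection residual is reported so callers can reject poor libraries.

**Shift-only echo mapping.** Two beats of equal period align spontaneously
over the whole cycle, so when the reference RR matches the echo RR the echo
events transfer by the pure shift `t ↦ t_R + (t − R1)`, where `t_R` is the
reference R-peak time and R1 the left R peak on the echo timeline. The
mapping refuses (rather than silently rescales) when the RR mismatch
exceeds a tolerance, default 2 %: beyond that the equal-period premise
fails and rescaling would reintroduce exactly the distortion the protocol
exists to avoid.

**DTW projection.** Reference fiducials move to any other beat along a
dynamic-time-warping path. Both clips are linearly resampled to a common
rate (default 500 Hz — 2 ms resolution while bounding the cost matrix) and
z-scored (amplitude drifts across beats; morphology is what matters). The
path minimizes the summed hybrid local cost

    c(i, j) = sqrt( α(i − j)² + β(xᵢ − yⱼ)² + γ(x′ᵢ − y′ⱼ)² + η(x″ᵢ − y″ⱼ)² )

over all paths satisfying monotonicity, continuity (unit steps (1,0),
(0,1), (1,1)), the boundary condition, and an optional Sakoe–Chiba window.
For each event, the reference sample index is located on the path and the
**median** of all matched target indices becomes the event time — a
one-to-many match occurs whenever the path runs vertically, and the median
is a deterministic, outlier-robust resolution. A projection that breaks the
physiological ordering Q ≤ MC ≤ AO ≤ AC ≤ MO is returned with a warning so
aggregation can drop the beat (beats so rejected are counted, not silently
ignored).

### Numerical choices in the DTW core

* **Sum, not mean.** The per-path mean cost is not decomposable by dynamic
  programming (path length K is unknown until the path ends), so the DP
  minimizes the path **sum**; the reported `total_cost` is the mean of the
  sum-minimal path. The brute-force enumerator in the test suite confirms
  the sum-minimal path exactly (floating-point equal) on hundreds of random
  instances.
* **Derivative units.** `derivative_series` exposes physical units (per
  second, per second²: central differences interior, one-sided edges). The
  projection cost, however, evaluates derivatives **per sample**
  (`DtwConfig.sampling_rate = 1`): at 500 Hz, per-second units multiply the
  slope and concavity terms by fs² and fs⁴, so the concavity term dominates
  the cost and — being a second difference — amplifies broadband noise
  until alignment degrades measurably. With per-sample units the four terms
  are commensurate at unit weights.
* **Default weights** α = 0 (gross shift is already handled by R-peak
  anchoring and resampling to a common grid), β = 1, γ = 1, η = 0.25. The
  weights are tunable per recording; no canonical values exist, and the
  defaults were chosen once on the synthetic generator's geometry.
* **Window** default 10 % of max(M, N) (half-width, plain |i − j| band);
  infeasible bands (narrower than |M − N|) raise instead of degrading.
* **Tie-breaking** in backtracking prefers the diagonal step, then the
  X-advance; paths are therefore deterministic functions of the inputs.
* **Slope constraint**: the unit-step pattern itself; no additional slope
  limit is imposed (none is standard for this application).

## Preprocessing

Linear detrend → zero-phase 4th-order Butterworth band-pass (ECG
0.5–40 Hz, SCG 1–45 Hz) → Daubechies-4 wavelet shrinkage with the soft
universal threshold (level 4, MAD noise estimate from the finest details),
then residual-mean removal. All parameters are configuration keys.

R peaks: Pan–Tompkins-style energy detector (5–15 Hz band, derivative,
square, 150 ms moving integral, threshold at 30 % of the maximum, 250 ms
refractory) refined to the local raw-signal maximum within ±50 ms. The Q
point is the signal minimum in the 80 ms window before an R peak (a
physiological bound on the QR duration). Beat sectioning cuts
`[R_i − 300 ms, R_{i+1} + 300 ms]`; the fixed margins stand in for T-wave
boundaries, whose delineation is out of scope.

One honest caveat: the conditioning chain is *not* numerically idempotent.
The 0.5 Hz high-pass corner has a zero-phase edge transient that decays
over seconds — longer than a beat-length clip — so conditioning an
already-conditioned clip changes it by a few percent (the passband gain
itself deviates from unity by only ~1e−5). The property test asserts
idempotence at 8 % relative on beat-length clips; filtering continuous
recordings before sectioning avoids most of the transient.

## Intervals, indexes, aggregation

LVET is defined as the ejection duration AC − AO, the positive-valued form
consistent with the physiological ordering. Missing events and
non-positive intervals raise errors naming the offending events. Per-beat
index pairs aggregate to per-subject mean and sample SD (n − 1 denominator;
SD = 0 at n = 1 by convention).

Both indexes are ratios of intervals, so they are invariant under a common
shift *and* a common rescale of all fiducial times. A uniform rescale
therefore biases individual fiducial timings (and any analysis of single
events) even where the two summary indexes happen to cancel the ratio — the
per-event error analysis is what distinguishes the methods.

## Validation statistics

`CohortValidation(records).fit()` produces, for a cohort table of
per-subject averaged indexes and clinical LVEF (stored as a fraction):

* three univariate OLS models of LVEF on PEP/LVET, Tei, and their mean,
  summarized by R²;
* four ROC analyses (predictors LVEF, PEP/LVET, Tei, mean index; positive
  class HFrEF, i.e. LVEF < 40 %). Scores are fitted probabilities of a
  univariate logistic GLM (logit link, binomial family); since the score is
  monotone in the predictor, the AUC equals the predictor's rank AUC with
  the appropriate sign — asserted as a test invariant. The operating point
  maximizes Youden's J = TPR − FPR, which coincides with the
  equal-cost/empirical-prior cost-slope criterion; the cutoff is mapped
  back to the predictor scale through the inverse logistic, landing on the
  deciding sample's value.

A packaged 56-subject reference table (sex, age, LVEF, diagnosis, cycle
count, per-subject index statistics) ships with the package; all its
headline statistics are recomputed, never stored.

## The synthetic generator

The generator emulates exactly the features the protocol depends on:

* **ECG**: Gaussian P-QRS-T components at known offsets from each R peak
  (Q at −30 ms);
* **SCG**: Gaussian-windowed 20 Hz bursts (σ = 12 ms) centered at each
  valve event, with per-event amplitudes (MC 0.6, AO 1.0, AC 0.8, MO 0.5)
  giving a realistic peak/valley structure; default event offsets from R:
  MC 25, AO 85, AC 385, MO 455 ms — plausible placeholders (IVCT 60 ms,
  ejection 300 ms, IVRT 70 ms), all configurable;
* **diastolic variability**: `vary_diastole` changes the RR interval while
  freezing all events at or before the 600 ms systolic boundary and
  scaling later events proportionally within the diastolic span — the
  mechanism that makes uniform rescaling biased and shift/DTW alignment
  accurate;
* **warps**: strictly monotone piecewise-linear maps with exact fiducial
  transport, for recovery experiments with analytic ground truth;
* **noise**: white Gaussian at a prescribed SNR; default sampling rate
  1000 Hz; every random draw flows from an explicit integer seed;
* **cohorts**: per-subject indexes drawn uniformly over a realistic range
  with LVEF following a known linear law plus Gaussian noise, HFrEF
  labeled below LVEF 0.40.

What the generator does **not** emulate: respiration and posture
modulation of the intervals, inter-subject SCG morphology differences,
motion artifacts, ectopic beats, and echo reading error. Passing the
synthetic experiments therefore demonstrates the correctness and internal
consistency of the alignment machinery under controlled morphology — not
clinical performance on real recordings.

## Experiment sizes and tolerances

The Monte-Carlo experiments use problem sizes chosen to estimate the rates
stably while keeping a full run in tens of seconds: 200 random instances
for oracle equivalence (sequence lengths ≤ 6, where exhaustive enumeration
is exact and tractable), 500 instances for the path-constraint suite
(lengths ≤ 40), 100 trials for projection recovery (±10 ms tolerance at
20 dB SNR, warp endpoint shifts up to ±60 ms — the 10 ms budget mirrors
the natural beat-to-beat fiducial variation), and 100 beat pairs with RR
differences of 30–120 ms for the method comparison. Under these
conditions the DTW projection's mean absolute fiducial error is ~1 ms
against ~18–19 ms for the conventional rescale, whose AC error exceeds its
MC error by an order of magnitude, as the geometry predicts
(error ≈ event offset × |ΔRR|/RR).

## Known limitations

* The DTW dynamic program is exact but dense: cost is O(M·N) in time and
  memory (banded when windowed); clips much longer than a few beats should
  be sectioned first.
* Projection quantizes event times to the common resampling grid (±1 ms at
  500 Hz).
* The conventional-alignment baseline implements the pure
  shift-plus-rescale geometry; scanner-specific echo timeline distortions
  are not modeled.
* The validation layer reports point estimates only (no confidence
  intervals on R² or AUC) and univariate models only.
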