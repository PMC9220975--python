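# scgdtw

Seismocardiogram (SCG) fiducial-point detection through **DTW-based
quasi-synchronous alignment**, with cardiac time intervals, diagnostic
indexes, and cohort-level validation statistics.

## The problem

Seismocardiography records chest-wall vibrations that carry the timing of
cardio-mechanical events — mitral valve opening/closure (MO, MC) and aortic
valve opening/closure (AO, AC). Locating these *fiducial points* in the SCG
yields the cardiac time intervals

```
PEP  = AO − Q        pre-ejection period
LVET = AC − AO       left-ventricular ejection time
IVCT = AO − MC       isovolumic contraction time
IVRT = MO − AC       isovolumic relaxation time
```

and the heart-rate-independent indexes **PEP/LVET** (contractility
coefficient) and **Tei = (IVCT + IVRT)/LVET** (myocardial performance
index), both negatively correlated with the left-ventricular ejection
fraction (LVEF).

Valve events are identified visually on echocardiograms, which are not
recorded simultaneously with home SCG measurements. The *conventional*
quasi-synchronous alignment bridges the two recordings by shifting and
**uniformly rescaling** one beat onto the other so the ECG R peaks
coincide — but a uniform rescale smears the beats' length difference over
the whole cycle, although real hearts absorb period differences almost
entirely in diastole. The detection error therefore grows with an event's
distance from the R peak: AC drifts by tens of milliseconds while MC barely
moves.

This package implements the improved protocol: select from the SCG
recording a **reference beat** whose RR interval matches the
echocardiogram's selected RR interval (so the echo events transfer by pure
shift, no rescaling), then **project** the reference fiducials onto every
other beat along a dynamic-time-warping path computed under a hybrid local
cost

```
c(i, j) = sqrt( α (aᵢ − bⱼ)²  +  β (xᵢ − yⱼ)²  +  γ (x′ᵢ − y′ⱼ)²  +  η (x″ᵢ − y″ⱼ)² )
```

that scores index shift, value, slope, and concavity differences, subject
to the monotonicity, continuity, boundary, warping-window, and slope (step
pattern) constraints with `max(M, N) ≤ K ≤ M + N − 1` for a path of length
K.

## Worked example

```python
import scgdtw as sg

# cohort validation on the packaged 56-subject reference table
results = sg.run_validation(sg.load_table1())
print(results.summary())
```

prints

```
Cohort validation results
============================================================
n = 56 subjects, 3876 heartbeat cycles
age    52.1 +/- 22.3 years
LVEF   50.8 +/- 16.3 %
cycles 69.2 +/- 16.2 per subject

Linear models (LVEF fraction vs predictor)
predictor       slope  intercept     R^2
pep_lvet       -1.614      0.998   0.768
tei            -1.169      1.043   0.860
mean_index     -1.476      1.070   0.894

ROC classification (positive = HFrEF)
predictor        AUC  opt FPR  opt TPR   cutoff
lvef           0.995    0.029    1.000    0.400
pep_lvet       0.937    0.229    1.000    0.290
tei            0.928    0.114    0.857    0.520
mean_index     0.949    0.200    1.000    0.375
```

Reading: LVEF declines by about 1.6 percentage points per 0.01 of PEP/LVET
(R² = 0.768); an LVEF threshold of 0.40 separates every HFrEF subject (TPR
= 1.0) at a 2.9 % false-positive rate, and the SCG-derived indexes alone
classify HFrEF with AUC ≈ 0.93–0.95.

The signal-level pipeline on synthetic beats with known ground truth:

```python
import scgdtw as sg

# project fiducials from a reference beat onto a warped, noisy copy
_, scg, _, truth = sg.generate_beat_pair(sg.BeatSpec(rr_ms=966.0, seed=0))
warp = sg.random_warp(scg.duration_ms, scg.duration_ms + 40.0, seed=1)
target, warped_truth = sg.apply_warp(scg, truth, warp)
projected, path = sg.project_fiducials(scg, truth, sg.with_noise(target, 20.0, seed=2))
```

A thin CLI mirrors the pipeline: `scgdtw simulate`, `scgdtw project`,
`scgdtw indexes`, `scgdtw validate-table1`, `scgdtw validate`.

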