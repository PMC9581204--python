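# Methods

## The model

The aortic valve opening area is expressed as a fraction of the LVOT
(left-ventricular outflow tract) cross-section and modelled as a function of
the LVOT-indexed peak transvalvular flow Q (m/s) and a dimensionless
relative valve stiffness s:

* linear: F₁(Q, s, θ₁, θ₂) = θ₁ · Q · θ₂ / s — proportional in Q, unbounded;
* sigmoid: F₂(Q, s, θ₃, θ₄, θ₅) = (θ₃ / s^θ₄) · (1/(1 + e^(−Q·θ₅)) − ½) —
  exactly zero at Q = 0, saturating at θ₃ / (2 s^θ₄).

Both are strictly increasing in Q and strictly decreasing in s; the
physically motivated difference is saturation: a valve cannot open beyond
its anatomical limit, so AVA must plateau at high flow. Indexing Q to the
LVOT (ml/s divided by mm², which is exactly m/s) and expressing AVA as an
LVOT fraction removes valve-size effects, which is what makes a single θ
usable across valves. In the ratio form of F₁, θ₁ and θ₂ are identified
only through their product; the package also provides the alternative
reading θ₁·Q·θ₂^s behind `linear_form="power"`.

Relative stiffness is an *operational* quantity: s = mean over the four
highest cardiac outputs (3.5–5.0 L/min) of the ratio of maximal cumulative
LV work, stiffened grade over native grade, with the native grade pinned at
s ≡ 1 by definition. The work integral W(T) = ∫₀ᵀ P_LV (dV/dt) dt is
evaluated trapezoidally (mmHg·ml/s → W via 133.322 Pa/mmHg and 10⁻⁶ m³/ml)
with the ejection-positive sign convention for dV/dt, and W_max is the
maximum of the cumulative series over the cycle. An alternative single
least-squares ratio across the four outputs is available
(`relative_stiffness(..., method="lsq")`); the default is the arithmetic
mean of the four per-output ratios.

## Fitting: modified leave-one-valve-out cross-validation

Per fold j (one per valve): θ̂ʲ = argmin_θ Σᵢ [AVAᵢ − F(Qᵢ, sᵢ, θ)]² over all
points of the K−1 training valves with their measured stiffness held fixed,
solved by Levenberg–Marquardt (`scipy.optimize.least_squares`, method
`"lm"`) from a fixed start — (1, 0.1) linear, (0.5, 1, 1) sigmoid — with
ftol = xtol = gtol = 1e-12 so repeated runs are bit-identical. Then, with
θ̂ʲ frozen, ŝ = argmin_s Σᵢ [AVAᵢ − F(Qᵢ, s, θ̂ʲ)]² once per grade of the
held-out valve; this one-dimensional problem is solved by the
trust-region-reflective variant with the bound s ≥ 10⁻³ (LM takes no
bounds), initialised at s = 1. Positivity of the sigmoid θ is not imposed
during optimisation; `ModelParams` validates it on the result.

The projection experiment repeats the test-phase fit per (held-out valve,
grade) using only the lowest 10 − n cardiac-output points (n ∈ {3, 5},
ranked by setpoint) and evaluates the model at the held-out highest
Q̄peak values. θ̂ʲ is reused from the fold's full training fit, not refitted.
Missing cells simply reduce the per-fold point counts; nothing is imputed.

Model comparison uses AIC = n·ln(MSE) + 2k with the natural logarithm and
k = number of hyperparameters + 1 (the residual-variance estimate): k = 3
for the linear model, k = 4 for the sigmoid. For the stiffness task n is
the number of (valve, grade) pairs; for the projection task n is the number
of projected points. Agreement statistics regress predicted on measured
(OLS), and report Pearson r, bias = mean(predicted − measured) with a
t-based CI of the mean, Bland–Altman limits of agreement bias ± 1.96·SD,
and CV% = 100·SD(differences)/mean(measured). The CV definition is one of
several in circulation; it is stated here because the quantity is reported
without a formula in most method-comparison write-ups.

## Signal processing

* **Delay estimation**: circular cross-correlation r(l) = (1/N)Σ x̄(n)y(n+l)
  over all N lags (FFT-based, equivalent to exhaustive search), argmax
  mapped to (−N/2, N/2], ties broken toward the smallest |l|. Positive lag
  means the first argument leads. Constant inputs return 0 with a warning.
* **Smoothing**: centered moving average with shrinking (truncated) windows
  at the edges — no padding data are invented; flow uses 800 samples
  (0.04 s at 20 kHz), AVA 40 frames (0.02 s at 2 kHz). Decimation keeps
  every 10th smoothed sample, exact because the camera rate divides the DAQ
  rate.
* **Flow**: Q_inst = d(position)/dt × piston area − Q_retro, central
  differences; position in cm and area in cm² give ml/s.
* **Ejection window**: the longest contiguous run with flow above 2 % of
  the beat maximum, with 5-sample hysteresis bridging dropouts. The window
  doubles as the valve-patency window for the gradient (mean of strictly
  positive ΔP = P_LV − P_ao samples).
* **Peak points**: all samples above 97 % of the maximal flow — pooled over
  every beat of a cell by default (`per_beat=True` applies the threshold
  within beats) — are averaged to give (Q̄peak, AVA‾peak).

## The synthetic generator

Defaults encode the reference experimental conditions: 11 valves × grades
(a, b, c) with
s\* = (1.00, 1.16, 1.34) × 10 cardiac outputs 0.5–5.0 L/min; sigmoid truth
θ\* = (0.72, 3.14, 2.80); AVA noise SD 0.02 (2 % of LVOT fraction — large
enough that model comparison is nontrivial, small enough that recovery
succeeds); indexed peak flow mapped linearly from the cardiac-output
setpoint (least squares through (0.5, 0.24), (2.5, 0.57), (5.0, 0.96)
L/min → m/s, i.e. slope 0.160, intercept 0.164), plus a per-valve offset
(SD 0.03 m/s) and per-cell jitter (SD 0.01 m/s); LVOT areas ~N(530, 40²) mm².
A single seed determines everything; the analytic point generator and the
waveform generator share one seeded per-cell target table, so the two
levels describe the same experiment.

Waveforms (per cell, tiled over 3 beats, fixed 60 bpm by default with a
fixed-stroke-volume alternative): the piston runs a flat-topped pulse —
raised-cosine ramps (6–45 ms) around a plateau (≥ 48 ms) whose height is
the cell's target peak flow, sized so the net forward volume matches the
cardiac-output setpoint. A plateau rather than a rounded peak is what a
constant-velocity piston produces, and it makes the 97 %-of-peak rule
measure a well-defined quantity. The retrograde (mitral-leak) flow is a
narrow Gaussian bump late in the up-ramp (amplitude 15 % of peak), which
carves the early-systolic notch into the transvalvular flow. Aortic
pressure rises to the 110 mmHg systolic target along a skewed sinusoid and
relaxes exponentially (two-element-Windkessel-like) to the 70 mmHg
diastolic target; LV pressure adds a gradient ∝ s^3.4 · Q_idx² during
ejection (gain 32 mmHg/(m/s)²) over an 8 mmHg baseline with short
isovolumetric ramps. The AVA channel follows the static sigmoid of
instantaneous indexed flow through a first-order opening/closing lag,
τ = 5 ms by default: the valve then reaches 95 % opening in ≈ 15 ms,
consistent with high-speed imaging of valve opening, and instantaneous AVA
tracks the plateau closely. (A slower τ is configurable; beyond ~10 ms the
measured AVA‾peak at the lowest outputs lags visibly below the static
curve, since the low-CO ejection plateau is only ~50 ms.) Channels are
circularly shifted by configurable known leads (camera +14 ms, flow probe
+3 ms relative to the DAQ) for the synchronization stage to undo.

What the generator does **not** emulate: beat-to-beat variability,
arrhythmia, sensor noise and drift, pressure-recovery phenomena, valve
bulging during isovolumetric contraction, and any fluid–structure
interaction. Passing tests therefore demonstrate the correctness and
internal consistency of the estimation machinery under the stated
generative model — not that a real valve follows F₂.

## Numerical and design choices

* Waveform-to-point closure (generator → signals → peak points matching the
  analytic table within 3 %) is checked with AVA noise off; the residual
  error is dominated by the 0.04 s moving-average attenuation of the flow
  pulse shoulders (~1 %).
* Problem sizes in tests: the full 11 × 3 × 10 factorial for everything
  point-level; waveform checks use 2–3 valves × up to 3 grades × 3–4
  outputs, which exercises every code path at a few seconds per case. The
  directional model-comparison replication uses seeds 1–20 at the full
  factorial.
* LV work at 5 L/min native grade lands near 1.4 J — the ~1 J regime of a
  physiological beat; the synthetic pressure gradient is deliberately only
  qualitatively calibrated (growing with stiffness and flow).
* Degenerate inputs: constant series in delay estimation warn and return 0;
  a gradient window with no positive samples warns and returns 0; a perfect
  fit (MSE = 0) makes AIC −∞ with a warning rather than raising.
* A training set with a single stiffness grade leaves the sigmoid's θ₃ and
  s^θ₄ confounded; the fit still runs (the cross-validation only needs
  relative predictions) but per-parameter values are not interpretable in
  that case.
* Fold structure ranks holdout points by cardiac-output setpoint, not by
  realized flow, so ties are impossible.
* Isostiffness lines are evaluated on 0.05–1.2 m/s in 0.01 m/s steps by
  default; grade-mean lines average curves pointwise (rather than refitting
  a pooled model) with a ± SE band, and group by grade label, not by
  numeric s.

## Known limitations

The linear model's two-parameter ratio form is overparameterised by design
(only θ₁θ₂/s is identified), matching its role as the clinical-assumption
baseline rather than a serious competitor. The stiffness construct measured
from LV work and the generative s\* are different objects; on synthetic
recordings the work-based s preserves the ordering of s\* but is not
numerically equal to it. The pipeline assumes strictly periodic beats with
a known rate; no beat detection is implemented.
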