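# Methods

## The task and the synthetic data

A tap at polar position (angle, distance) on a rigid plate launches a
surface wave at a single speed *c*.  Sensor *k* at position **r**ₖ emits one
first spike at `t(k) = ‖p − rₖ‖ / c` (plus noise); decoders only ever see
differences of these timestamps — the stimulus onset is unknown to them by
construction, and every decoder in the package is shift-invariant (tested
per module).

The generator (`wave_sim`) emulates a recorded session on a wooden plate:

- **Geometry.**  Eight sensors at 45° parametric steps on a 150 mm × 100 mm
  ellipse, centroid at the origin.  The ellipse is deliberately
  non-circular (a circular ring collapses the multilateration system to
  rank < 4) and its 300 mm major axis gives a 1–1.5 ms opposite-sensor
  propagation time at 200–300 m/s.  The minor axis makes the linear system
  worst-conditioned for stimuli at 90°/270°, which inflates range errors
  there without harming angle recovery (measured by
  `analytic.conditioning_profile`; the mirror symmetry of the conditioning
  is exact).
- **Wave speed.**  Default 126 m/s — the value a distance-vs-delay
  regression yields on a tapped wooden surface; any value in 50–300 m/s is
  supported.
- **Noise.**  (i) i.i.d. Gaussian jitter per spike (default σ = 20 µs);
  (ii) a fixed per-sensor bias drawn once per dataset from N(0, 50 µs) —
  this makes repeated recordings cluster systematically rather than
  scatter, the dominant error mode of a real sensor front-end; (iii)
  quantization of timestamps to the 1 µs ADC tick.  Defaults chosen so that
  angle decoding is easy and distance decoding is marginal.
- **What it does not model.**  Amplitude and attenuation, dispersion,
  reverberation, multiple sources, and — importantly — *per-position*
  systematic timing signatures.  Real recordings give each
  (position, sensor) pair its own reproducible offset; the generator's bias
  is per-sensor only.  Consequently passing tests show that each algorithm
  behaves as designed on clean TDOA geometry plus stationary noise; they do
  not certify performance on hardware data, and one published behavior
  (perfect distance recovery by the phasor model, see below) demonstrably
  *requires* those per-position signatures.

An optional waveform path synthesizes a damped sinusoid per sensor
(carrier 1 kHz, decay 5 ms — invented, used only to exercise level-crossing
extraction) and returns the first upward level crossing.

## Analytic multilateration

With reference sensor 1 and ΔT₁ⱼ = tⱼ − t₁, each non-reference sensor
gives a linear equation in X = [u, v, c·d, c²]:

    (x₁−xⱼ)u + (y₁−yⱼ)v − ΔT₁ⱼ·(cd) − (ΔT₁ⱼ²/2)·c² = (x₁²+y₁²−xⱼ²−yⱼ²)/2

solved by the normal-equation pseudoinverse.  The ½ factors are required
for the identity to hold exactly (verified row-by-row against the expanded
distance equations and against a nonlinear least-squares solver);
formulations that drop them do not recover noiseless inputs.  The solver
works internally in metres/seconds to keep AᵀA well-scaled, reports the
condition number of A, and flags (rather than clamps) solutions whose
decoded c² is non-positive — under noise this happens on ill-conditioned
instances and silently clamping would hide it.

## Delayed-coincidence detectors

Wave speed is estimated by ordinary least squares of source–sensor distance
on first-spike delay over all (trial, sensor) pairs.  Because the decoder
cannot know each trial's onset, both variables are centred within each
trial (equivalent to per-trial intercepts); a constant per-sensor bias then
moves only intercepts, never the slope.  Noiseless recovery is exact to
< 0.1 %.

Detector delays synchronize all arrivals at the latest one; the membrane is
a sum of unit-weight causal exponentials with τ = 100 µs (below the
inter-sensor delay spread, so only true coincidences pile up; exposed in
config).  Since the membrane only decays between arrivals, its maximum is
evaluated exactly at the delayed arrival times.  The firing threshold per
detector minimizes the empirical count of false negatives plus false
positives by a single descending sweep; ties in v_max are swept
negatives-first, which makes every intermediate count correspond to a
realizable threshold and the sweep provably equal to exhaustive search
(property-tested on tied instances).  Classification is argmax of
v_max − θ, ties to the lowest index.

Phenomenology on default noise: angle accuracy stays at 100 % while
distance accuracy degrades toward chance (25 %) as systematic bias grows —
same-angle different-distance positions produce nearly proportional delay
patterns that coincidence cannot separate under bias.

## Phasor (complex weights and delays)

Latency is encoded as phase over the window T = 2·r_max/c (the maximal
geometric arrival spread), so phases of physical spikes live in [0, π];
spikes outside the window trigger a warning (with a 2 µs slack since
on-axis stimuli attain the bound exactly).  One complex weight vector per
position is fitted by one-vs-rest least squares over all trials, and the
decode w = |ŵ|, d = (T/π)·arg ŵ is an exact bijection with the re-encode
(tested to 1e-12).  Decoded delays may be negative — they are regression
artifacts, not physical delays.  The decision statistic is Re(ŷ) (a
large-modulus wrong-phase response should not win); |ŷ| is also exposed.

**Known limitation.**  On geometry-only synthetic data the four same-angle
distance clusters are nearly collinear in phasor space: even a max-margin
linear readout cannot separate 2 of the 32 positions one-vs-rest, and the
least-squares argmax recovers all angles but only ~60 % of distances,
train = test.  Perfect distance recovery by this model therefore depends on
per-position systematic timing signatures present in real recordings and
absent from the generator by design.  The acceptance suite records the
claimed distance figure and is expected to fail on it; this is a property
of the data model, not of the regression.

## Temporal difference encoder network

TDE *k* takes facilitation from sensor *k* and trigger from the opposite
sensor *k+4*.  A trigger spike is accepted only if the facilitating trace
is positive *at its arrival* — this makes the response to the reversed
order exactly zero — and injects I = I_trig·f, which decays with the
product of two τ_syn = 1 ms traces.  The response peak decreases
monotonically with the spike-time difference (verified numerically over
(0, 5 τ_syn]).

The inverse-direction ring receives weak (1×) input from adjacent TDEs and
strong (4×) from the opposite TDE, producing an activity minimum at the
stimulus direction.  Sixteen direction neurons are inhibited through the
cosine profile w = w_peak·max(0, cos(θᵢ − φⱼ)) with a slow (20 ms)
inhibitory synapse and excited by uniform sensor-driven background delayed
by 6 ms, so inhibition is established before the background arrives.  The
scalar background weight is grid-searched on a calibration set to maximize
one-hot-ness (fraction of trials with ≥ 1 vote minus 0.1 × mean extra
votes); direction neurons carry a 10 ms refractory period so each votes at
most once per stimulus.  All constants (τ_m = 10 ms, thresholds 20 mV above
rest, R_m = 10 MΩ) are config-exposed.

The wiring is exactly 8-fold rotation symmetric, so permuting the input
spike vector by one sensor index permutes every ring's output bitwise (the
*stimulus-angle* rotation is only approximate on the elliptical array).
On a rotationally balanced dataset with symmetric noise the vote-error
distribution is mirror-symmetric and its circular mean is 0 in expectation;
the sample mean is checked against its circular standard error.  Cardinal
stimuli yield clean one-hot votes; diagonal stimuli produce extra
neighbouring votes (the ellipse breaks the 45° symmetry), widening the
circular standard deviation without biasing the mean.  Per-trial
classification reads out the *first* vote, which is the most reliable (the
matching neuron escapes inhibition first).

Time stepping is exponential-Euler at dt = 0.1 ms; halving dt moves
first-spike times by less than two coarse steps (threshold crossings near
tangency can shift by more than one).

## Synaptic delay plasticity

Closed-form bi-exponential membrane (τ_m = 2 ms, τ_syn = 0.5 ms, both well
above the 0.1 ms input resolution), one spike per synapse, membranes reset
between patterns.  The first neuron to cross threshold wins (ties to the
lowest index) and only its delays move:

    dᵢ ← max(0, dᵢ + η·g(t_fire, sᵢ))

where the update kernel g is EPSP-shaped — zero at coincidence, peaked one
EPSP rise-time before the post-spike — so arrivals that preceded the spike
are pulled later, toward it, and repeated wins synchronize the winner's
arrivals (the arrival-time spread strictly decreases on a repeated
pattern).  The kernel is deliberately *not* the exact partial derivative
∂V/∂sᵢ of the closed form (which carries extra 1/τ factors and is exposed
as `gradient(form="exact")`, verified against finite differences to 1e-6);
the exact derivative implements gradient ascent toward the EPSP peak and
also synchronizes, but the EPSP-shaped kernel matches the intended
zero-at-coincidence behavior and is the default.  Two scale choices matter
and are documented as this package's own calibration:

- the update interprets the kernel on the volt scale (mV/1000), giving
  ~0.01 ms of delay change per win at η = 1 (η decays 10 % per 100
  patterns); on the raw mV scale the update diverges;
- R_m = 1 MΩ with I_inj = 180 nA makes a *single* EPSP subthreshold for
  N ≥ 3 connections while the aligned compound EPSP is suprathreshold —
  if single EPSPs fire the neuron, the WTA rewards nothing but the
  earliest arrival and specialization collapses (measured).

Specialization is scored by a frozen (η = 0) pass: a neuron is specialized
when > 80 % of its wins fall on one angle, and coverage is the fraction of
the 8 angles claimed by at least one specialized neuron.  With 50 neurons,
4 random connections each, and one pass over the clean 320-trial dataset,
coverage is 100 % on 10/10 seeds; the sparsity sweep (independent random
connectivities per N) reproduces the qualitative trend of near-complete
coverage from N = 2 upward.  Distance is not decoded — membrane maxima are
nearly identical across distances at the same angle, and the package keeps
that negative result.

## Structural plasticity (EI network)

Alpha-kernel input synapses (peak w exactly τ_syn after the pre-spike) feed
excitatory LIF neurons; any excitatory spike drives the inhibitory
population, which hyperpolarizes all excitatory neurons (WTA; within-step
ties resolve to the largest threshold margin, and interneurons enforce the
lockout from the next step).  On each neuron's first spike per
presentation:

- weight STDP with decaying windows both sides (the growing-with-lag
  depression variant is switchable but diverges, so the conventional
  window is the default), plus multiplicative decay w ← w(1 − κη) that
  keeps weights off the bimodal rails;
- time-constant STDP Δτ = a_τ·(Δt−s)·e^(−|Δt−s|/(τ*−s))/((τ*−s)e⁻¹) with
  Δt = t_post − t_pre, so early channels grow slower synapses and late
  channels faster ones — this is the sign the stated behavior requires and
  the opposite of a literal t_pre − t_post reading;
- a threshold step +2 mV; presentations nobody captures lower all
  thresholds by 4 mV.  Thresholds start *above* every achievable response
  and descend until neurons sparsely capture patterns, FEAST-style.

Structural re-spawning replaces all 8 synapses of a neuron whose mean
weight has decayed below 0.1·w_max (checked every 10 presentations) with
fresh Gaussian draws, w ~ N(0.5, 0.2)·w_max and τ_syn ~ N(0.6, 0.3) ms.
The membrane is fast (τ_m = 0.5 ms) and the synapses sub-millisecond: at
these scales the compound response depends on the coincidence structure of
the EPSCs rather than their total charge, which is what makes pattern
selectivity possible at all — with 10 ms membranes the response is nearly
pattern-independent (measured ~1 mV spread) and no parameter setting
specializes.

Evaluation freezes the synapses and scores one pass with thresholds fixed
at their per-neuron average over four live warm-up cycles: the homeostatic
threshold saws around the separating level, so the cycle average is the
settled operating point while any snapshot is biased by sawtooth phase.
With 4 excitatory / 2 inhibitory neurons and 4 clean patterns presented 20
times each, the modal outcome over seeds is all 4 patterns captured by
exactly one neuron; full one-to-one specialization (distinct owners) is a
slower process and is reliable (~90 % of seeds) by 100 presentations per
pattern.  The 32-neuron / 32-pattern configuration runs and reports partial
convergence — same-angle different-distance patterns are too similar under
jitter for distinct owners, reproducing the published failure mode.

## Problem sizes and numerical choices

Simulations use dt = 0.1 ms (TDE, EI network) or the closed form on a
0.1 ms grid (delay plasticity); datasets are the full 320-trial session
except where a module's experiment calls for single patterns.  The
acceptance script evaluates the TDE on 8 angles × 4 distances × 3
repetitions, the plasticity modules on 10 seeds each, and everything else
on full 320-trial datasets.  Exponentials are masked before evaluation to
avoid overflow on non-causal times; all randomness flows through
`numpy.random.default_rng` seeds, and every reported experiment is
bit-reproducible given its seed.
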