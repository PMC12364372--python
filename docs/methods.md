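# Model and methods

## The network

`attnet` simulates a two-layer network of Poisson spiking neurons built to
study how top-down feature-based attention can be relayed through a
population with mixed selectivity, and how the degree of structure in the
inter-layer wiring controls whether attentional feedback generalizes across
retinotopic locations.

**Sensory layer.** Eight independent ring sub-networks of 512 neurons.
Neuron *i* of a ring prefers the angle θᵢ = 360·i/512 degrees of a circular
feature space (orientation, hue, motion direction). Within a ring, the
weight between neurons *i* and *j* is a difference of circular normal
(von Mises) kernels of the preferred-angle offset θ = θᵢ − θⱼ:

    w(θ) = λ + A·exp(k1(cos θ − 1)) − A·exp(k2(cos θ − 1)),   w(0) = 0

with A = 2, k1 = 1 (excitation width), k2 = 0.83 (suppression width).
Because k1 > k2 the suppression lobe is wider than the excitation lobe, so
the kernel is relatively excitatory at short range and inhibitory at long
range; its first circular harmonic is positive (≈ +11 summed over a ring),
which lets a stimulated ring form a localized bump, while the narrow
suppression lobe keeps the harmonic weak enough for two bumps 180° apart to
coexist — a prerequisite for simulating attention between two overlapping
stimuli.

*Choice of the baseline λ.* λ shifts the kernel uniformly and thereby sets
the ring's net uniform coupling Σⱼ w(θᵢⱼ) = 512·(λ − 0.0975). A positive
baseline of the size used in the wide-suppression parent parameterization
(λ = +0.28 with k2 = 0.25) would, combined with the narrowed suppression
kernel, make that sum strongly positive (+93): the quiescent state is then
linearly unstable and the whole network saturates within ~50 ms, and w(π)
would be positive, leaving no inhibition between opposite-tuned neurons.
A strongly negative baseline (λ = −0.28) restores the parent model's
uniform inhibition but makes the two 180°-apart bumps fight a
winner-take-all battle that annihilates the unattended stimulus. We
therefore set λ = 0: the kernel is a pure difference of von Mises lobes,
the uniform coupling is mildly inhibitory (−50), the spontaneous sensory
rate sits at the quiescent point of the transfer function (~2–3 Hz), two
bumps coexist stably, and attentional modulation shifts the two
contrast-response functions in opposite directions in the graded way the
task requires. This is the one constant of the model we had to calibrate
rather than adopt; everything else below is used at its published value.

**Control layer.** 1024 neurons with no recurrent connections among
themselves. Each control neuron is connected reciprocally (feedforward +
feedback over the same adjacency) to sensory neurons in all eight rings,
each pair connected with probability p = 0.35. Weights are balanced so a
uniformly active network delivers zero net drive: an excitatory feedforward
connection onto control neuron *i* carries α/Nexcᵢ − α/4096 and every input
(connected or not) carries the broad inhibition −α/4096, with α = 2100 and
Nexcᵢ the neuron's excitatory in-degree; feedback weights are built the
same way with β = 200 and divisor N_second = 1024. Every row of both
matrices sums to zero (checked to 10⁻⁹·α). Mixed selectivity is inherited:
a control neuron responds to a sensory bump exactly insofar as its random
sample of connections happens to over-cover the bump.

**Structured wiring (κ).** The `kappa_structure` parameter biases which
sensory neurons a control neuron connects to. Each control neuron draws one
preferred angle μ uniformly from the 360 integer degrees; its partners in
every ring are then drawn without replacement with probability proportional
to exp(κ·cos(θ − μ))/(2πI₀(κ)). κ = 0 is fully random wiring; κ = 0.4 makes
like-tuned neurons across rings converge onto common control neurons.
Connection counts per (control neuron, ring) are Binomial(512, 0.35) in
both cases (a per-pair Bernoulli mode is available for the fully random
case and is statistically equivalent there). Rows or columns that end up
with no excitatory connection — possible only at toy sizes — are resampled
or repaired and logged, keeping the balancing formulas well defined.

## Dynamics

Each neuron carries a synaptic activation s with time constant τ = 10 ms.
The summed input gᵢ = Σⱼ Wᵢⱼ sⱼ + driveᵢ maps to an instantaneous rate
through a baseline-shifted hyperbolic tangent

    r = 0.4·(1 + tanh(0.25·g − 3))     [spikes/ms]

giving a ceiling of 0.8 spikes/ms (800 Hz) and a quiescent rate r(0) ≈
0.002 spikes/ms (~2 Hz). Spikes are drawn per step by Bernoulli thinning of
the inhomogeneous Poisson process (p = r·dt, at most one spike per neuron
per step; r·dt ≤ 0.08 at the default dt = 0.1 ms). The per-step update
order is fixed: rates are computed from pre-decay activations, activations
decay by exp(−dt/τ), spikes are drawn, spiking neurons' activations are
incremented. Order effects vanish as dt → 0; a refinement test checks that
halving dt leaves windowed rates statistically unchanged.

**Synaptic saturation.** The activation is bounded at s_max = 1 (a
saturating gating variable: a spike drives s to its ceiling rather than
incrementing it without bound). This is the second modelling choice we had
to make beyond the published constants: with unbounded activations the
reciprocal loop between the layers — an excitatory feedforward connection
of ~1.5 per unit activation answered by reciprocal feedback onto exactly
the neurons that caused it — amplifies its own Poisson fluctuations and
ignites from rest (control rates > 300 Hz, all stimulus selectivity
drowned). With s ≤ 1 the loop saturates gracefully and the quiescent state
is stationary (~2–3 Hz sensory, ~40 Hz control with strong skew). All
reported phenomena require this quiet operating point.

**Drives.** A stimulus of strength S at angle μ adds
S·exp(κ_in·cos(θᵢ−μ))/(2πI₀(κ_in)) to the target ring's neurons (κ_in =
14), truncated to zero beyond 3σ with σ = 1/√κ_in radians (the large-κ von
Mises ↔ Gaussian correspondence). Simultaneous stimuli to one ring sum.
Additive attention adds S_att to the rate argument of each targeted control
neuron during the stimulus epoch; multiplicative attention instead scales
the targeted neurons' summed feedforward input by S_att (our reading of the
multiplicative variant; isolated behind the `mode` switch, with S_att = 1
the no-modulation baseline).

## Task protocols

*Sensory task:* one of 16 stimuli uniformly tiling (0°, 360°] (22.5°, 45°,
…, 360°) is presented alone to sub-network 0 at strength 10 for 300 ms;
rates are averaged over the last 250 ms. Control neurons are rank-ordered
by their mean rate to the to-be-attended stimulus and the top
⌊0.2·1024⌋ = 204 become the targets of top-down modulation (floor count;
rate ties broken by neuron index).

*Attention task:* two stimuli at 90° and 270° (always 180° apart) are
presented to sub-network 0 while the targeted control neurons receive
additive modulation. The full published grid is stimulus strength 0–19 ×
modulation 0–18 step 2 × attended ∈ {90°, 270°}, 50 trials per condition,
1000 ms trials; the desk-scale defaults used by the test-suite and the
acceptance script are documented below. Per-condition seeds derive from
(master seed, condition index) so any condition block is independently
reproducible.

*Multi-seed driver:* `run_experiment` rebuilds the topology per
initialization seed and repeats sensory task → targeting → attention task,
returning per-seed data and across-seed mean ± SEM summaries.

## Analyses

*Contrast-response functions.* For each condition cell, the mean windowed
rate of the two ring neurons nearest the attended angle, and nearest the
unattended angle (ties broken by index). Gain is quantified by fitting

    R(c) = Gr·cⁿ/(cⁿ + Gcⁿ) + b,    c = strength/19

with Gr fixed to the curve's max − min and b to its min, and (Gc, n) free:
a dense grid (Gc ∈ [−1, 1] step 0.01; n ∈ [−10, 10] step 0.1) minimizing
RMSE, refined by bounded L-BFGS-B from the grid optimum. Numerical edges:
c = 0 with n < 0 is evaluated in the limit (ratio → 1); candidates whose
model value is not real (negative Gc with non-integer n) are excluded by a
non-finite guard; for even integer n the sign of Gc is unidentifiable and
ties break toward Gc ≥ 0; a flat curve (Gr = 0) is flagged and skipped.
The self-consistency oracle draws (Gc, n) from the identifiable region
(Gc ∈ [0.05, 1], n ∈ [0.3, 8] — outside it the model value is not real or
the curve is flat) and fixes (Gr, b) at their generating values, because
the data-driven fixing Gr = max − min systematically understates Gr for
non-saturating curves and biases (Gc, n) by design.

*Circular regression decoding.* Two chained empirical-Bayes ridge
regressions (scikit-learn BayesianRidge in a RegressorChain, default
hyperpriors) predict sin and cos of the stimulus angle — chain order fixed
sin-then-cos and recorded — and the angle is recovered with atan2 on the
(0°, 360°] convention. Errors are wrapped absolute differences (≤ 180°;
90° is the uniform-guess chance level). The decoder is validated on the
sensory task by leave-one-trial-per-stimulus-out cross-validation, then
trained on all sensory-task trials of a sub-network and tested on
attention-task trials of the same sub-network (cross-generalization from
stimulus-driven to attention-driven activity), separately per condition
cell and per sub-network. Raw per-trial predictions are kept alongside the
MAE so pooled or reflected histogram views can both be built.

*SVM decoding.* A linear SVC (default regularization, raw windowed rates,
no standardization — a flag exists but defaults off) classifies the
attended stimulus within each sub-network with leave-one-trial-per-class-out
cross-validation (with 50 trials per class: 50 folds of 98 train / 2 test),
and cross-generalizes between unstimulated sub-networks over all 7×6 = 42
ordered train/test pairs (train on all trials of one, test on all of the
other).

## Desk-scale problem sizes

All functional results use the full-size network (8×512 + 1024): reduced
networks concentrate α over fewer connections and sit in a
fluctuation-dominated regime with no stimulus selectivity, so size cannot
be traded for time. Time is saved instead on trials and integration:

- attention trials: 400 ms stimulus, no pre-stimulus epoch, the published
  last-250-ms window (steady state is reached well before the window;
  CRFs match 1000 ms trials within sampling error);
- 8–10 trials/condition, 2 initializations (10 in the full protocol);
- dt = 0.125 ms in the heavy end-to-end fixtures (ceiling rate × dt = 0.1,
  the validity bound of the thinning; checked by the dt-refinement test);
  dt = 0.1 ms everywhere by default.

The miniature fixture network (8×64 + 128, all constants unchanged) is
used only for structural and API tests, for the regime reason above.

## What the tests do and do not show

The synthetic protocols here are the model's own study conditions — there
is no external data. Passing tests show that the implementation reproduces
the architecture's qualitative repertoire: bump coding with accurate
single-trial decoding; selective, rank-based control-neuron targeting;
leftward/rightward contrast-gain shifts of attended/unattended curves;
chance-level feature information in unstimulated sub-networks under random
wiring with above-chance *consistency* (within-sub-network SVM) that does
not transfer across sub-networks; and the emergence of spatially global,
transferable feature signals as wiring structure κ grows. They do not show
anything about biological tissue, and one quantitative magnitude —
the mean attended-rate increase of ~10–20% at modulation strengths 2–4 —
is not reproduced at our operating point: the increase is much larger
(order 100%+) in every stable regime we found, and the corresponding check
is left failing rather than tuned (see the repository's test suite).

## Known limitations

- No cell types, refractoriness, conduction delays, plasticity, or injected
  noise beyond the Poisson spiking itself.
- The published constant set of this architecture is dynamically
  inconsistent as printed; the
  two repairs above (λ = 0 baseline, s_max = 1 saturation) are this
  package's modelling choices and are the main caveat when comparing
  quantitative magnitudes with the original report.
- Trials are statistically independent (state reset between trials); no
  inter-trial carry-over.
- The batched engine draws each condition block from its own counter-based
  stream; results are bit-reproducible for a fixed protocol but not
  spike-for-spike identical across different batch layouts.
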