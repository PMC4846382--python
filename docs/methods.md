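# Methods

## Scope and models

The package implements two complementary models of rhythm generation in a
heterogeneous excitatory network, plus the analysis layer that turns raw
simulations into burst tables, quantal-regime labels and phase-plane
geometry.

The **large-scale model** is a population of N = 100 single-compartment
conductance-based neurons with five currents (fast Na⁺, persistent Na⁺,
delayed-rectifier K⁺, leak, excitatory synaptic). All constants live in
`model_core` with the published values; only the leak reversal `E_L`
(−62.0 ± 0.93 mV) and the persistent-sodium conductance `ḡ_NaP`
(5.0 ± 0.5 nS) vary across neurons, drawn from independent untruncated
Gaussians (a non-positive conductance draw — probability ~1e−23 — is
redrawn). The "±" values are treated as standard deviations; the source
tables do not state SD vs SEM explicitly. Connectivity is directed
Bernoulli(p) with uniform weight w and no self-edges; the synaptic equation
indexes weights asymmetrically (w_ji), and nothing requires symmetry.

The **reduced model** replaces each excitability cluster with one non-spiking
activity unit carrying `(V, h_NaP)` and a piecewise-linear output `f(V)`.
Three units (E_L = −54.5, −59.0, −63.5 mV; HE, ME, LE) are coupled
all-to-all with weight w.

## Integration

*Large-scale:* exponential Euler with step dt = 0.1 ms. Each relaxation
variable advances by `x ← x_∞ + (x − x_∞)·exp(−dt/τ)` with `x_∞, τ` evaluated
at the step-start voltage; the membrane equation is put in the same form via
`τ_V = C/Σg`, `V_∞ = Σ(gE)/Σg`. **Sweep order matters at this step size**: the
gates are updated first and the voltage update then uses the fresh gate
values (a Gauss–Seidel sweep). With the alternative ordering (voltage from
step-start gates) the 0.1 ms step collapses multi-spike bursts into
single-spike oscillations and mislocates burst periods by a factor ~3; the
gates-first sweep matches an adaptive LSODA reference to <0.2% in burst
period at dt = 0.1 ms (test-enforced to <1%). Halving dt changes the
uncoupled burst period by <2%.

Synaptic conductances decay exactly (`exp(−dt/τ_SynE)`) and receive an
instantaneous increment `ḡ_SynE·w_ji` per presynaptic spike; the
single-state incremental form is algebraically identical to the explicit
sum of exponential kernels over the full spike history (test-verified to
1e−10). A spike is an upward crossing of −35 mV between consecutive steps
(at most one per step; crossing semantics make a refractory guard
unnecessary); increments are applied at the start of the step after
detection, with no conduction delay.

*Reduced:* classical fixed-step RK4 at dt = 0.5 ms (no method is prescribed
for this model; convergence is checked by step halving, <0.5% period
change). The model is deterministic; default initial conditions are
V = −60 mV and h spread over [0.4, 0.6].

An option to slave the fast persistent-sodium activation `m_NaP` to its
steady state exists but is **not** a faithful approximation: under dt
refinement to 0.002 ms the slaved and dynamic variants converge to different
periodic solutions (587 ms single-spike vs 1938 ms multi-spike bursting at
E_L = −61.8 mV) — the ~1 ms activation lag is dynamically essential. The
dynamic gate is the default.

## Initial conditions and transients

Per-neuron initial states are drawn uniformly (V ∈ [−70, −50] mV,
h_NaP ∈ [0.2, 0.8], fast gates at steady state, g_syn = 0) from a seed
stream independent of the population and topology streams, so any one
ingredient can be resampled alone. A startup transient (20 s for census
runs; 10 s for the 50 s regime runs, leaving the final 40 s) is discarded
before any analysis, which makes results insensitive to the initial-state
ranges (they are chosen, not published).

## Burst detection and regime labels

Population activity is a histogram of all spikes per 10 ms bin. Bursts are
segmented as maximal runs of bins at or above 5 spikes/bin, merging runs
separated by less than 50 ms (segmentation is package plumbing; only the
classification rules are published). Two LA rules coexist deliberately:

* **peak rule** (main analyses): LA iff peak > 50 spikes/bin (strict: a peak
  of exactly 50 is SA);
* **window rule** (parameter sweeps): LA iff some 100 ms window within the
  burst holds more than 20 spikes;
* **participation rule** (mechanism-level, package addition): LA iff the
  burst recruits ≥90% of the population — useful where background tonic
  firing contaminates amplitude-based rules.

A segmented "event" spanning ≥90% of the analysis window is sustained tonic
activity, not a burst, and is excluded from burst counts. The quantal label
1:N uses N = total burst events per LA-to-LA period (equivalently 1 + the
SA count between consecutive LA bursts), the definition consistent with the
printed "N−1 SA bursts between each pair of LA bursts"; a reduced-model
regime is called stable only after five consecutive periods with identical
event counts, otherwise "irregular". Per-neuron firing modes use ISI
grouping: a gap > 300 ms starts a new burst; silent = no spikes; tonic =
spiking with no supra-gap ISI; bursting otherwise.

Reduced-model events are maximal intervals with f(V) > 0.05 (small but
robust to numerical ripple); overlapping per-unit events merge into network
events, and an event is LA exactly when the LE unit participates.

## Phase-plane analysis

The V-nullcline has the closed form
`h(V) = −[ḡ_L(V−E_L) + drive·ḡ_SynE(V−E_SynE)] / [ḡ_NaP m_∞(V)(V−E_Na)]`,
with the synaptic drive frozen as a scalar parameter (the quasi-static
approximation the analysis itself relies on). Knees are located by a fine
grid scan plus bounded scalar refinement (|Δh| < 1e−8); fixed points by
bracketed root-finding on the nullcline difference; stability from the
trace/determinant of a numerically differentiated Jacobian. Mode
classification is primarily by fixed-point branch (left = silence, middle =
bursting, right = tonic); near the cusp where the folds merge the branch
label is ambiguous and a *stable* fixed point is classified by its output
level instead (f > 0.05 → tonic). Classification agrees with long-run
simulation at every point of a 0.1 mV E_L scan over [−66, −50] mV.

## What the generator emulates — and what it does not

The built-in population/connectivity generator *is* the study's input: there
is no external data. It reproduces distributed excitability, mild
conductance heterogeneity and sparse random excitation, but none of the
biological features outside the model class — no inhibition, no other
burst-supporting currents (I_CAN, I_h, I_A, Ca²⁺-dependent K⁺), no
distance-dependent or small-world topology, no channel noise. Passing tests
therefore demonstrate properties of this model family, not of slices.

## Known limitations and honest discrepancies

Implemented exactly as printed (verified against an independent adaptive
integrator and dt refinement), the single-neuron conditional-bursting window
at ḡ_NaP = 5 nS is E_L ∈ [−62.3, −61.4] mV, which yields ≈35 silent /
≈50 bursting / ≈15 tonic neurons under the default distributions rather
than the 49/45/6 split the original figures report, and the class boundaries
shift by ≈0.5 mV per nS of ḡ_NaP, so the silent→bursting→tonic ordering
along E_L cannot be exact under a 0.5 nS conductance SD. Downstream of this
offset: the coupled network produces genuine amplitude-rule MMOs around
w = 1.8–3, p = 0.15 (LA peaks 54–74 spikes/bin, IBI-after-LA ≫
IBI-after-SA), but the modal SA count between LA bursts at w = 1.8 is
0–3 and irregular rather than a stable 5; and at (w = 3.0, p = 0.24) the
network enters a self-sustained ~60 Hz tonic reverberation that persists at
low ḡ_NaP (it does not require I_NaP), so no suppression boundary exists at
that operating point — while at (w = 3.0, p = 0.15) the same code produces
the expected LA rhythm. In the reduced model the LE unit first activates at
w ≈ 1.05 (robust to upward/downward weight ramps; no hysteresis), although
the quantal staircase w = 1.7/2/3/4 → 1:5/1:4/1:2/1:1 is reproduced
exactly. For the excitability-perturbation protocol both printed magnitudes
(8% and 10%) are exposed; at 10% all three units fall silent, at 8% HE
continues at reduced rate with LE quiescent (ME is still occasionally
recruited).

## Problem sizes

Default analysis runs are 50 s simulations of the 100-neuron network with
the final 30–40 s analyzed, and 300 s reduced-model runs after a 50 s
transient; the excitability scan covers 161 E_L values at 200 s each and
the weight scan 51 values at 300 s each. These sizes give stable modal
regime labels and census counts (regime labels are unchanged between 200 s
and 350 s reduced runs).
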