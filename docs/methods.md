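# Methods

This note documents the models and procedures implemented in
`microtrauma`, the defaults they use, and what the synthetic-data tests
do and do not establish about real recordings.

## Phase synchronization and the eigenvalue indices

Each neuron's event train (calcium-transient onsets, or burst onsets in
the simulator) is converted to an instantaneous phase that advances by
2π per inter-event interval:

    φ(t) = 2πn + 2π (t − tₙ) / (tₙ₊₁ − tₙ),   tₙ ≤ t < tₙ₊₁.

The phase is sampled on a 10 Hz grid (matching the acquisition rate of
the fluorescence recordings the analysis is designed for) and is
undefined outside `[first event, last event)`; undefined samples are
excluded from every average. The pairwise synchronization matrix is the
circular concentration of the phase difference,

    S_jk = | ⟨ exp(i(φ_j(t) − φ_k(t))) ⟩_t |  ∈ [0, 1],

averaged over the intersection of the two neurons' phase supports.
Pairs with less than 5 s of common support are reported as missing and
excluded downstream.

Significance comes from surrogate ensembles. For each eigenmode *k* of
`S` (eigenvalues λ_k, M neurons) against the surrogate mean λ̄′_k and
standard deviation SD_k:

    SynIndex_k = (λ_k − λ̄′_k) / (M − λ̄′_k)   if λ_k > λ̄′_k + 2·SD_k,
                 0                             otherwise,

and the global synchronization index SI is the maximum over modes:
0 for uncoordinated activity, exactly 1 for a fully synchronized
ensemble (where λ_max = M). The per-neuron participation index is

    PI_i = min(1, max_k SynIndex_k · M · v²_ik)

over significant modes with eigenvectors v_k; a fully synchronized
network gives PI_i = 1 for every neuron (uniform leading eigenvector),
and a neuron carrying no weight in any significant mode gets PI ≈ 0.
The exact participation formula in the antecedent literature is not
printed anywhere we could verify, so this convention — chosen so the
perfect-synchrony case is exact — is validated by property tests, not
by published values.

Functional edges are declared where S_jk exceeds the (1−α) quantile of
the surrogate ensemble's S′_jk (α = 0.05, 39 surrogates by default);
the connectivity index is CI_j = degree(j)/(M−1), so a neuron
synchronized with every other neuron has CI = 1. Modularity Q of the
resulting graph is Newman's Σ_c (e_cc − a_c²), computed through
networkx (greedy agglomeration when no partition is given); a complete
graph treated as one community gives Q = 0 exactly.

## Two surrogate nulls

A single surrogate construction cannot serve both statistics, and the
package deliberately uses two:

* **Eigenvalue test (SI, PI): amplitude-adjusted Fourier-transform
  (AAFT) surrogates of the sampled phase series**, with ~10 iterations
  of spectrum/amplitude refinement (the standard IAAFT polish — the
  single-pass version whitens the spectrum enough to shift the lag-1
  autocorrelation by ~0.1). Each surrogate holds exactly the original
  sample values in an order with approximately the original spectrum;
  independently surrogating each neuron destroys all cross-neuron
  alignment, so a synchronized ensemble stands far above the null and
  the identical-trains case yields SI = 1.
* **Edge test (CI): Fourier phase randomization of the unit phasor
  exp(iφ)**, renormalized to the unit circle. Two independent neurons
  firing at the same mean rate drift slowly in relative phase, which
  elevates their S_jk by chance; a null that preserves each phasor's
  power spectrum — hence its autocorrelation, which sets that chance
  level — is required for the false-edge rate to track α. Measured on
  independent same-rate trains, the phasor null gives a false-edge rate
  of ~0.05–0.12, where the phase-series AAFT null gives ~0.86. The
  phasor null is *not* used for the eigen test because it degenerates
  for strictly periodic trains (a linear phase ramp's phasor is a pure
  tone, whose only spectrum-preserving surrogates are rotations).

## Transient detection

Traces are normalized to ΔF/F against a baseline window (mean F₀ must
be positive). Two detectors are provided and agree on clean input:

* **Wavelet**: Ricker (mexican-hat) CWT over scales spanning 0.3–3 s
  transient widths. The noise floor is estimated from the first
  difference of ΔF/F and propagated to each scale through the wavelet's
  impulse-response norm; candidate peaks must persist across ≥ 2
  consecutive scales. Three scales were tried first and rejected:
  transients with a neighbor 0.5–1.2 s away merge at the coarse scales,
  breaking the longer ridge and biasing the rate estimate low.
* **Template**: normalized cross-correlation against the known
  difference-of-exponentials transient kernel (rise 0.1 s, decay 1 s),
  threshold 0.8, with a rising-onset check that rejects decay tails.

Both feed a matching-pursuit post-stage: onsets are refined by a local
matched filter, kernel amplitudes are fitted jointly (with an intercept
absorbing baseline error), one modal unit-amplitude kernel per onset is
subtracted, and the residual is re-scanned for events that had merged
with a neighbor. Coincident doubles — isolated onsets carrying ≳1.6×
the unit amplitude — contribute one extra event. On synthetic traces at
SNR 5 this pipeline detects transients with F1 ≈ 0.96 and recovers a
0.35 Hz Poisson event rate with bias ≈ −0.02 Hz.

Per-cell response metrics follow the recording conventions: F_max/F₀
(responder when > 2), ∫F dt over the first 60 s after a stimulus, and
latency measured as the first crossing of half the post-stimulus ΔF/F
maximum. Response classes around a stimulus are total and exclusive:
poration when fluorescence falls below 10% of baseline within 5 s
(operationalizing "collapse within seconds"), else primary for
responders with latency < 0.5 s, secondary for latency ≥ 0.5 s, else
none.

## The microcircuit simulator

Sixty leaky integrate-and-fire point neurons occupy a 10,000 µm² square
field. Wiring: each neuron contacts Poisson(20) distinct targets drawn
with weights ∝ exp(−d/50 µm); exactly round(n/6) neurons are inhibitory
(1:5 I:E); a fifth of the excitatory cells are intrinsically bursting
(IB) and carry a low-threshold calcium current. Dendrite counts are
truncated-normal(5, 2), minimum 1, and every synapse is assigned to a
dendrite of its target.

Synapses hold 80 AMPA + 20 NMDA receptors (excitatory) or 12 GABA
receptors (inhibitory) at 12/45/40 pS; each connection comprises 8
dendritic contacts. Receptor gating is stochastic: the open count of a
pool is Binomial(N, p(t)) where p(t) is a difference-of-exponentials
kernel summed over recent presynaptic spikes (AMPA 0.5/3 ms, NMDA
5/80 ms, GABA 1/10 ms; per-spike peak open probabilities 0.8/0.5/0.8),
clipped to [0, 1]. This binomial-kernel scheme is a parametric stand-in
for particle-simulation receptor profiles and reproduces their mean and
count-noise structure without the particle machinery.

Currents, integrated by forward Euler at 2 ms over 60 s:

* I_syn = Σ_r −g_r (V_m − E_r) N_r^open, with the NMDA term gated by
  the magnesium unblock probability
  P = 1/(1 + exp(−0.062 V_m)·[Mg]/3.57) ([Mg] defaults to the 0.8 mM of
  the recording saline);
* I_rest = −g_L (V_m − E_rest), g_L = 10 nS, E_rest = −65 mV
  (τ_m = 20 ms at C = 200 pF);
* I_KCa = −g_KCa [Ca]_i (V_m − E_K), g_KCa = 1500 nS/mM, E_K = −90 mV —
  the burst terminator;
* I_LT = g_LT m∞²(V) h (120 − V) for IB cells only, g_LT = 8 nS, with a
  slow (0.5 s) inactivation gate that de-inactivates during the
  calcium-driven afterhyperpolarization and fires the rebound that
  paces the next burst;
* a stereotyped spike (V jumps to +30 mV for one sample, resets to
  −65 mV, 4 ms refractory clamp) at the −50 mV threshold.

Calcium: ions enter through open NMDA channels at
g_NMDA·|V_m|·N_open/(Z_Ca·e) ions/s — the printed-form arithmetic is
exposed unchanged in `calcium_influx_ions` — multiplied in the dynamics
by the Mg-unblock probability, because calcium can only pass unblocked
channels (without that factor the standing NMDA flux at rest holds
~9 µM of calcium, and the resulting tonic K(Ca) current silences the
network). 90% is buffered at the spines; the free remainder, plus a
3 µM increment per action potential (voltage-gated entry), accumulates
in a 2 pL cell with 1 s first-order clearance above a 100 nM baseline.

Background drive models innervation from outside the modeled field:
independent 50 Hz Poisson events per neuron, each activating an
800-receptor AMPA-like pool. Under these defaults the control network
fires synchronized population bursts at ~0.32 events/s per neuron with
SI ≈ 0.75–0.85 and a functionally complete baseline graph (mean
CI ≈ 1.0) — the phenotype of mature cultured networks. The unstated
constants above (contacts per connection, per-spike calcium, T-current
size, background strength, cell volume, g_KCa, clearance) were fixed
once while calibrating to that control phenotype and are all
overridable in `SimConfig`.

Injury clamps [Ca]_i of a uniformly sampled subset (round(fraction·n)
neurons) at the extracellular 2 mM for 60 s; clamped cells cannot fire
and release no transmitter. Scenario toggles: `ttx` disables all
spiking, `bmb` zeroes the GABA conductance. Runs are deterministic
given a seed, and construction, injury sampling and dynamics use
separate streams so a zero-fraction injured run is bit-identical to its
control.

For the dose-response experiment, metrics are computed on burst-onset
trains (spikes preceded by ≥ 0.3 s of silence — the discrete events a
calcium indicator would report). The field-of-view SI treats neurons
with no events as zero rows of the sync matrix (a dropped-out cell
coordinates with nobody), mirroring how silent cells enter an imaging
analysis; CI naturally assigns them degree 0. Over injured fractions
{0, 0.13, 0.25, 0.50, 0.75}, SI_post/SI_pre and CI_post/CI_pre decline
strictly monotonically and near-linearly, and the calcium-oscillation
amplitude of the *uninjured* cells collapses sharply once more than
~30% of the network is clamped — the cooperative burst fails to ignite.

## Outcome models

Severity grades a field by its responder fraction into half-open bins
A = [0.75, 1], B = [0.50, 0.75), C = [0.25, 0.50), D = [0, 0.25)
(boundary fractions go to the higher grade; encoded ordinally D=0…A=3
for regression). Regions by distance from the epicenter: injured
≤ 200 µm < penumbra ≤ 500 µm < distal.

Logistic regression of the binary 6 h fate on the eight per-cell
predictors (PI/CI/rate before and after injury, severity grade,
distance) is maximum likelihood via IRLS (statsmodels), with
per-feature likelihood-ratio χ² tests from refits without the feature;
perfect separation is flagged, not fatal. Fisher LDA computes the
within-class (W) and total (T) scatter matrices, Wilks' Λ = det W/det T,
the discriminant direction Σ⁻¹(μ₁−μ₀) with pooled Σ = W/(n−K), and a
correct-prediction rate from the Gaussian discriminant rule with
empirical priors (the prior term matters: synthetic fate data are
~10% dead, where a midpoint threshold loses ~19 accuracy points).
Resubstitution accuracy is reported by default, matching the
experimental convention the analysis mirrors; 5-fold CV is available
and labeled. Λ is affine invariant and is cross-checked in tests
against a brute-force scatter oracle and sklearn's LDA.

## Synthetic data

The generator provides every input format the analysis consumes, with
ground truth attached. Event trains use a common-mother construction: a
mother Poisson process at the population rate is thinned per neuron
with probability `sync_level` and topped up with independent events at
rate (1−sync)·rate, then Gaussian-jittered — per-neuron rate is the
base rate at every synchrony setting, trains are identical at
sync = 1/jitter = 0 and independent Poisson at sync = 0. Fluorescence
is F₀·(1 + A·Σ kernel(t−tₖ)) + Gaussian noise at 10 Hz, with a
difference-of-exponentials kernel (0.1 s rise, 1 s decay — GCaMP-like
at this sampling rate). Injury signatures paint a calcium plateau
(default dwell 30 s before recovery; the in vitro dwell is not
characterized, so this is a free parameter) whose peak interpolates
from 291% over baseline within 100 µm of the epicenter to 143% beyond
400 µm, with primary latencies < 0.5 s near the center and secondary
latencies 0.5–5 s increasingly likely with distance; porated cells
(< 5% by default) decay exponentially to zero with a 1 s constant.
Fate labels are Bernoulli draws from a known logistic model on the
eight predictors whose default slopes make death rise with severity and
proximity and fall with network integration; the per-cell predictors
degrade post-injury by independent Beta factors (independent, so the
post features are identifiable in recovery tests). The mPAD generator
lays posts on a hexagonal 4 µm grid and displaces them by F/k plus
localization noise.

What the generator does **not** emulate: pixel-level movies and ROI
segmentation, astrocyte biology (the distance/latency rule is a
phenomenological stand-in for the ATP wave), photobleaching and drift,
indicator nonlinearity/saturation, and spatially correlated noise.
Passing tests therefore demonstrate that the analysis chain is correct
under its own forward model — rate recovery, F1, parameter recovery and
the dose-response shape — not that those accuracies transfer
quantitatively to arbitrary recordings.

## mPAD calibration

During-pulse centroids are matched to before-pulse posts by nearest
neighbor; matches beyond half the 4 µm pitch, or double-claimed posts,
are errors listing the offenders. Forces are F = k·x with
k = 7.22 nN/µm, and pressure over the post cross-section is
P = F/(π(d/2)²) with d = 1.83 µm; in these units 1 nN/µm² = 1 kPa
exactly, so the calibrated 0.4–1.2 nN force band corresponds to
0.15–0.46 kPa ≈ 0.022–0.066 PSI. Pressure figures computed over other
reference areas (e.g., the pulse footprint rather than the post face)
will differ by the area ratio; the module reports its area and formula
alongside every estimate for this reason.

## Numerical and testing choices

All randomness flows through `numpy.random.Generator` objects seeded at
the interface; seeds are recorded in file headers and manifests.
Problem sizes in the test suite (60 s recordings, 10–20 neurons per
synthetic set, 10-seed injury sweeps, 25–50 surrogates) were chosen as
the smallest at which the targeted statistics stabilize. Degenerate
inputs fail loudly: too-short recordings, non-positive baselines,
all-NaN traces, degenerate surrogate ensembles (mean eigenvalue ≥ M),
single-class fate tables, ambiguous post matching, non-finite membrane
voltages.

Known limitations: the simulator is a phenomenological point-neuron
model — its unstated currents (I_KCa, I_LT, spike shape, background)
are standard forms validated by property tests, not fits to
electrophysiology; the detection pipeline assumes the generator's
kernel family; the edge-significance null is calibrated for same-rate
renewal-like trains and has no power against strictly periodic
identical inputs (where rhythm-preservation makes synchrony the null
expectation); and CI uses the (M−1) denominator so that "connected to
every other neuron" maps to exactly 1.
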