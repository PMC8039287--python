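# microtrauma

Simulation and analysis of **micromechanical injury in cultured neural
networks**. When individual neurons in an in vitro cortical microcircuit
are mechanically injured — a model of the cellular-scale damage pattern
of traumatic brain injury — the network's synchronized calcium activity
degrades in a graded, quantifiable way, and a cell's pre- and
post-injury activity predicts whether it survives. This package
implements the complete computational chain of such experiments for
researchers studying network-level injury and recovery:

* a **stochastic integrate-and-fire microcircuit** (60 neurons,
  AMPA/NMDA/GABA receptor pools with binomial gating, voltage-dependent
  magnesium block, NMDA calcium influx) with a graded injury protocol
  that clamps a chosen fraction of cells at 2 mM intracellular calcium,
  plus TTX/bicuculline scenario toggles;
* a **calcium-imaging analysis stack**: ΔF/F normalization, transient
  detection (Ricker-wavelet ridges or template correlation, with a
  matching-pursuit second pass), and functional-network metrics;
* **cell-fate statistics**: severity grades A–D, injured / penumbra /
  distal regions, logistic regression with likelihood-ratio tests, and
  Fisher LDA with Wilks' Λ;
* **micro-post array (mPAD) calibration**: post displacement → force
  (F = k·x, k = 7.22 nN/µm) → pressure over the post cross-section;
* a **synthetic-data generator** for every input the analysis consumes,
  with ground truth attached, so the whole chain is testable without
  experimental recordings.

## The core statistic

Each neuron *j* with event times *t_j(n)* gets an instantaneous phase
φ_j(t) = 2πn + 2π(t − t_j(n))/(t_j(n+1) − t_j(n)). The pairwise
synchronization matrix is the circular concentration of the phase
difference,

    S_jk = | ⟨ e^{i(φ_j(t) − φ_k(t))} ⟩_t |  ∈ [0, 1],

and significance comes from surrogate ensembles: with eigenvalues λ_k
of S and surrogate eigenvalues λ′_k (mean λ̄′_k, spread SD_k),

    SynIndex_k = (λ_k − λ̄′_k)/(M − λ̄′_k)  if λ_k > λ̄′_k + 2·SD_k, else 0,

and the **global synchronization index** SI = max_k SynIndex_k runs
from 0 (uncoordinated) to 1 (fully synchronized). Per-neuron
**participation** (PI) weights SynIndex by the squared eigenvector
loadings; the **connectivity index** CI_j is the fraction of the other
M−1 neurons with a surrogate-significant pairwise sync; **modularity**
Q summarizes the functional graph. See `docs/methods.md` for the full
model descriptions, defaults and caveats.

## Worked example

Generate a synthetic 20-neuron, 60 s recording at the 0.35 Hz baseline
rate of a mature culture, detect transients at SNR 5, and compute the
network metrics:

```python
import numpy as np
from microtrauma.synth import SynthNetworkSpec, generate_spike_trains, \
    spikes_to_fluorescence
from microtrauma.detect import compute_dff, detect_transients
from microtrauma.netmetrics import SpikeTrainSet, compute_network_metrics

spec = SynthNetworkSpec(n_neurons=20, duration=60.0, base_rate=0.35,
                        sync_level=0.8, seed=7)
trains, truth = generate_spike_trains(spec)
traces = spikes_to_fluorescence(trains, spec, noise_sd=10.0)   # SNR 5

events = []
for i in range(traces.n_neurons):
    dff = compute_dff(traces.traces[i], slice(0, traces.traces.shape[1]))
    events.append(detect_transients(dff, fs=10.0))

detected = SpikeTrainSet(events, spec.duration)
nm = compute_network_metrics(detected, n_surrogates=50, seed=7)
print(f"mean detected rate : {detected.rates().mean():.3f} Hz")
print(f"global SI          : {nm.global_si:.3f}")
print(f"mean PI / mean CI  : {np.nanmean(nm.pi):.3f} / {nm.ci.mean():.3f}")
print(f"modularity Q       : {nm.modularity_q:.3f}  ({len(nm.edges)} edges)")
```

```
mean detected rate : 0.362 Hz
global SI          : 0.476
mean PI / mean CI  : 0.476 / 0.958
modularity Q       : 0.000  (182 edges)
```

The detector recovers the 0.35 Hz generator rate; at `sync_level=0.8`
the network is partially synchronized (SI ≈ 0.5), almost every pair is
a significant functional edge (CI ≈ 0.96), and the near-complete graph
has no community structure (Q = 0).

Injuring the simulated microcircuit degrades the same metrics in a
dose-dependent way:

```python
from microtrauma.sim import SimConfig, injury_experiment, run_simulation

pre = run_simulation(SimConfig(seed=1))
for f in (0.25, 0.50):
    r = injury_experiment(SimConfig(seed=1, injury_fraction=f),
                          n_surrogates=39, pre=pre)
    print(f"fraction {f:.2f}: SI ratio {r['si_ratio']:.2f}, "
          f"CI ratio {r['ci_ratio']:.2f}, amplitude ratio {r['amp_ratio']:.2f}")
```

```
fraction 0.25: SI ratio 0.30, CI ratio 0.48, amplitude ratio 0.66
fraction 0.50: SI ratio 0.11, CI ratio 0.12, amplitude ratio 0.34
```

Clamping a quarter of the cells halves the network's connectivity;
clamping half collapses synchrony and the calcium-oscillation amplitude
of the cells that were *not* injured — the cooperative population burst
fails once too much of the circuit is silenced.

A `microtrauma` command-line interface mirrors the modules
(`synth`, `simulate`, `detect`, `metrics`, `fate`, `mpad`, `pipeline`);
`microtrauma pipeline --config cfg.yaml --outdir out/` chains the
stages and writes a manifest with seeds and output hashes.

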