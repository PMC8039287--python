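"""Stochastic leaky integrate-and-fire microcircuit with graded injury.

The model reproduces, in silico, the degradation of a cultured cortical
network under micromechanical trauma:

* 60 point neurons placed uniformly in a 10,000 um^2 square field,
  wired by random axon extension with a Poisson out-degree of expected
  value 20 and distance-weighted target selection; a 1:5 ratio of
  inhibitory to excitatory neurons; a fifth of the excitatory cells
  carry an intrinsic-bursting (IB) low-threshold calcium current.
* Synapses from excitatory cells hold 80 AMPA and 20 NMDA receptors;
  inhibitory synapses hold 12 GABA receptors.  Single-channel
  conductances are 12, 45 and 40 pS.  Receptor gating is stochastic:
  the open count of each pool is a binomial draw around a
  difference-of-exponentials kernel driven by presynaptic spikes.
* NMDA current is gated by the voltage-dependent magnesium-unblock
  probability ``1 / (1 + exp(-0.062 Vm) * [Mg] / 3.57)``.
* Membrane voltage follows ``C dV/dt = I_rest + I_KCa + I_LT +
  I_spike + I_syn`` on a 2 ms forward-Euler grid over 60 s, with a
  stereotyped spike and a 4 ms refractory clamp at threshold crossing.
* Calcium enters through open NMDA channels at a rate
  ``g_NMDA * |Vm| * N_open / (Z_Ca * e)`` ions per second; a fixed
  fraction is buffered at the spines and the free remainder accumulates
  per cell with first-order clearance.  The calcium-gated potassium
  current this drives is what terminates population bursts, so the
  control network oscillates slowly and synchronously, as mature
  cultures do.
* Injury clamps intracellular calcium of a sampled subset of neurons at
  2 mM (the extracellular level) for 60 s, disabling their spiking and
  silencing their outgoing drive.  Scenario toggles emulate TTX (no
  spiking anywhere) and bicuculline (GABA conductance zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .netmetrics import (
    SpikeTrainSet,
    _sync_from_phases,
    connectivity,
    phase_series,
    sync_indices,
)

__all__ = [
    "SimConfig",
    "Network",
    "SimResult",
    "ReceptorPool",
    "build_network",
    "mg_unblock_prob",
    "receptor_open_counts",
    "synaptic_current",
    "calcium_influx_ions",
    "apply_injury",
    "membrane_step",
    "run_simulation",
    "injury_experiment",
    "injury_sweep",
]

ELEMENTARY_CHARGE_C = 1.602e-19
AVOGADRO = 6.02214076e23

#: inter-spike gap that starts a new population event (burst onset), s
BURST_GAP_S = 0.3


@dataclass
class SimConfig:
    """All simulator constants.  Defaults follow the modeled culture.

    Structural and kinetic values with an experimental basis: 60 nodes
    in a 10,000 um^2 field, expected out-degree 20, a 1:5
    inhibitory:excitatory split, 80/20/12 AMPA/NMDA/GABA receptors per
    synapse at 12/45/40 pS, a 2 ms step over 60 s, and a 2 mM / 60 s
    calcium clamp for injured cells.  The remaining electrophysiological
    constants are standard LIF choices documented in the methods note.
    """

    n_neurons: int = 60
    field_area_um2: float = 10_000.0
    expected_neighbors: float = 20.0
    inhibitory_fraction: float = 1.0 / 6.0      # 1:5 I:E
    ib_fraction: float = 0.2                    # of excitatory cells
    axon_decay_um: float = 50.0
    dendrite_mean: float = 5.0
    dendrite_sd: float = 2.0

    n_ampa: int = 80                            # receptors per excitatory synapse
    n_nmda: int = 20
    n_gaba: int = 12                            # receptors per inhibitory synapse
    synapses_per_connection: int = 8            # dendritic contacts per connection
    g_ampa_ns: float = 0.012                    # 12 pS
    g_nmda_ns: float = 0.045                    # 45 pS
    g_gaba_ns: float = 0.040                    # 40 pS
    e_ampa_mv: float = 0.0
    e_nmda_mv: float = 0.0
    e_gaba_mv: float = -70.0

    # receptor kernel time constants (rise, decay), ms
    tau_ampa_ms: tuple[float, float] = (0.5, 3.0)
    tau_nmda_ms: tuple[float, float] = (5.0, 80.0)
    tau_gaba_ms: tuple[float, float] = (1.0, 10.0)
    # peak open probability contributed by a single presynaptic spike
    p_peak_ampa: float = 0.8
    p_peak_nmda: float = 0.5
    p_peak_gaba: float = 0.8

    c_m_pf: float = 200.0
    g_leak_ns: float = 10.0
    e_rest_mv: float = -65.0
    v_threshold_mv: float = -50.0
    v_reset_mv: float = -65.0
    v_spike_mv: float = 30.0
    refractory_s: float = 0.004
    e_k_mv: float = -90.0
    g_kca_ns_per_mm: float = 1_500.0
    g_lt_ns: float = 8.0
    tau_h_lt_s: float = 0.5

    mg_mm: float = 0.8                          # recording-saline magnesium
    z_ca: int = 2
    e_charge_c: float = ELEMENTARY_CHARGE_C
    cell_volume_pl: float = 2.0
    buffer_fraction: float = 0.9                # spine buffering of entering Ca
    tau_ca_s: float = 1.0
    ca_baseline_mm: float = 1e-4                # ~100 nM resting
    ca_per_spike_mm: float = 0.003              # VGCC entry per action potential

    # independent background excitatory drive (spontaneous release)
    bg_rate_hz: float = 50.0
    bg_receptors: int = 800

    dt_s: float = 0.002
    t_total_s: float = 60.0
    injury_fraction: float = 0.0
    injury_clamp_mm: float = 2.0
    injury_duration_s: float = 60.0
    scenario: str = "control"                   # control | ttx | bmb
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.t_total_s <= 0:
            raise ValueError("dt and total time must be positive")
        if not 0.0 <= self.injury_fraction <= 1.0:
            raise ValueError("injury_fraction must lie in [0, 1]")
        if self.expected_neighbors >= self.n_neurons:
            raise ValueError("expected_neighbors must be below n_neurons")
        if self.scenario not in ("control", "ttx", "bmb"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.mg_mm < 0:
            raise ValueError("[Mg] must be non-negative")


@dataclass
class Network:
    """Static wiring produced by :func:`build_network`."""

    positions: np.ndarray            # (n, 2) um
    phenotype: np.ndarray            # 'exc_rs' | 'exc_ib' | 'inh'
    w_exc: np.ndarray                # (n_post, n_pre) excitatory synapse counts
    w_inh: np.ndarray                # (n_post, n_pre) inhibitory synapse counts
    dendrite_counts: np.ndarray      # per neuron
    synapse_dendrite: list[tuple[int, int, int]]   # (pre, post, dendrite)

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    def out_degree(self) -> np.ndarray:
        return (self.w_exc + self.w_inh).astype(bool).sum(axis=0)


@dataclass
class ReceptorPool:
    """One synapse-level receptor population with stochastic gating.

    The open count at time ``t`` is ``Binomial(n_total, p_open(t))``
    where ``p_open`` is a difference-of-exponentials kernel (peak
    ``p_peak`` per presynaptic spike) summed over recent spikes and
    clipped to [0, 1].
    """

    n_total: int
    tau_rise_ms: float
    tau_decay_ms: float
    p_peak: float = 0.8

    def _norm(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        tpk = np.log(td / tr) * tr * td / (td - tr)
        return float(np.exp(-tpk / td) - np.exp(-tpk / tr))

    def open_probability(self, spike_times_ms: np.ndarray, t_ms: float) -> float:
        dt = t_ms - np.asarray(spike_times_ms, dtype=float)
        dt = dt[dt >= 0]
        k = np.exp(-dt / self.tau_decay_ms) - np.exp(-dt / self.tau_rise_ms)
        return float(np.clip(self.p_peak * k.sum() / self._norm(), 0.0, 1.0))

    def open_count(
        self, spike_times_ms: np.ndarray, t_ms: float, rng: np.random.Generator
    ) -> int:
        return int(rng.binomial(self.n_total, self.open_probability(spike_times_ms, t_ms)))


@dataclass
class SimResult:
    """Trajectories and spike output of one simulation run."""

    config: SimConfig
    network: Network
    spike_trains: list[np.ndarray]           # s
    event_trains: list[np.ndarray]           # burst onsets, s
    v_traces: np.ndarray                     # (n, steps+1) mV
    ca_traces: np.ndarray                    # (n, steps+1) mM
    time: np.ndarray                         # (steps+1,) s
    injured: np.ndarray                      # bool per neuron
    seed: int | None


def build_network(config: SimConfig, rng: np.random.Generator | None = None) -> Network:
    """Place neurons and wire them by random axon extension.

    Nodes are uniform in the square field; each node connects to
    ``Poisson(expected_neighbors)`` distinct targets drawn with weights
    decaying exponentially in distance, so nearby neurons are favored.
    Exactly ``round(n/6)`` nodes are inhibitory.  Dendrite counts come
    from a truncated normal; every synapse is assigned to one dendrite
    of its postsynaptic cell.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    side = float(np.sqrt(config.field_area_um2))
    pos = rng.uniform(0.0, side, (n, 2))
    n_inh = int(round(n * config.inhibitory_fraction))
    phen = np.array(["exc_rs"] * n, dtype=object)
    inh_idx = rng.choice(n, n_inh, replace=False)
    phen[inh_idx] = "inh"
    exc_idx = np.setdiff1d(np.arange(n), inh_idx)
    n_ib = int(round(exc_idx.size * config.ib_fraction))
    if n_ib:
        phen[rng.choice(exc_idx, n_ib, replace=False)] = "exc_ib"

    dend = np.maximum(1, np.round(rng.normal(config.dendrite_mean, config.dendrite_sd, n))).astype(int)
    w_exc = np.zeros((n, n))
    w_inh = np.zeros((n, n))
    syn_dend: list[tuple[int, int, int]] = []
    d = np.hypot(pos[:, 0][:, None] - pos[:, 0], pos[:, 1][:, None] - pos[:, 1])
    for pre in range(n):
        k = min(int(rng.poisson(config.expected_neighbors)), n - 1)
        if k == 0:
            continue
        w = np.exp(-d[pre] / config.axon_decay_um)
        w[pre] = 0.0
        targets = rng.choice(n, size=k, replace=False, p=w / w.sum())
        for post in targets:
            if phen[pre] == "inh":
                w_inh[post, pre] += 1
            else:
                w_exc[post, pre] += 1
            syn_dend.append((pre, int(post), int(rng.integers(dend[post]))))
    return Network(
        positions=pos, phenotype=phen, w_exc=w_exc, w_inh=w_inh,
        dendrite_counts=dend, synapse_dendrite=syn_dend,
    )


def mg_unblock_prob(v_m_mv: np.ndarray | float, mg_mm: float) -> np.ndarray | float:
    """Probability that an NMDA receptor is free of its magnesium block.

    ``P = 1 / (1 + exp(-0.062 * Vm) * [Mg] / 3.57)`` with Vm in mV and
    [Mg] in mM — monotone increasing in Vm, exactly 1 at [Mg] = 0.
    """
    if mg_mm < 0:
        raise ValueError("[Mg] must be non-negative")
    v = np.asarray(v_m_mv, dtype=float)
    out = 1.0 / (1.0 + np.exp(-0.062 * v) * mg_mm / 3.57)
    return float(out) if np.isscalar(v_m_mv) else out


def receptor_open_counts(
    pool: ReceptorPool,
    spike_times_ms: np.ndarray,
    t_ms: float,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Stochastic open-receptor count of one pool at time ``t``."""
    return pool.open_count(spike_times_ms, t_ms, np.random.default_rng(rng))


def synaptic_current(
    v_m_mv: np.ndarray | float,
    open_counts: dict[str, np.ndarray | float],
    config: SimConfig,
    p_unblocked: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Total receptor current ``sum_r -g_r (Vm - E_r) N_r`` in pA.

    The NMDA term is additionally scaled by the magnesium-unblock
    probability (computed from Vm when not supplied).
    """
    v = np.asarray(v_m_mv, dtype=float)
    if p_unblocked is None:
        p_unblocked = mg_unblock_prob(v, config.mg_mm)
    i = (
        -config.g_ampa_ns * (v - config.e_ampa_mv) * open_counts.get("ampa", 0.0)
        - config.g_nmda_ns * (v - config.e_nmda_mv) * open_counts.get("nmda", 0.0) * p_unblocked
        - config.g_gaba_ns * (v - config.e_gaba_mv) * open_counts.get("gaba", 0.0)
    )
    return float(i) if np.isscalar(v_m_mv) else i


def membrane_step(
    v_m_mv: np.ndarray | float,
    total_current_pa: np.ndarray | float,
    dt_s: float,
    c_m_pf: float,
) -> np.ndarray | float:
    """Forward-Euler membrane update ``V' = V + dt/C * sum(I)``.

    Units: mV, pA, s, pF (so ``dt*1e3/C`` converts to mV).  Spike
    thresholding, the stereotyped spike shape and the refractory clamp
    are applied by the caller.
    """
    v = np.asarray(v_m_mv, dtype=float) + dt_s * 1e3 / c_m_pf * np.asarray(
        total_current_pa, dtype=float
    )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("membrane voltage diverged")
    return float(v) if np.isscalar(v_m_mv) else v


def calcium_influx_ions(
    v_m_mv: np.ndarray | float,
    n_nmda_open: np.ndarray | float,
    dt_s: float,
    config: SimConfig | None = None,
) -> np.ndarray | float:
    """Calcium ions entering through open NMDA channels in one step.

    The NMDA calcium flux ``g_NMDA * |Vm| * N_open / (Z_Ca * e)`` is an
    ion rate (ions per second); one step admits ``rate * dt`` ions,
    before spine buffering.
    """
    if config is None:
        config = SimConfig()
    g_s = config.g_nmda_ns * 1e-9                    # S
    v_v = np.abs(np.asarray(v_m_mv, dtype=float)) * 1e-3
    rate = g_s * v_v * np.asarray(n_nmda_open, dtype=float) / (
        config.z_ca * config.e_charge_c
    )
    out = rate * dt_s
    return float(out) if np.isscalar(v_m_mv) else out


def apply_injury(
    config: SimConfig, network: Network, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample the injured subset: ``round(fraction * n)`` neurons.

    Injured neurons have intracellular calcium clamped at the
    extracellular 2 mM for the 60 s injury window, cannot spike, and
    release no transmitter.  Returns the boolean injury mask.
    """
    rng = np.random.default_rng(rng)
    n = network.n_neurons
    n_injured = int(round(config.injury_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if n_injured:
        mask[rng.choice(n, n_injured, replace=False)] = True
    return mask


def _events_from_spikes(spikes: np.ndarray, gap_s: float = BURST_GAP_S) -> np.ndarray:
    """Burst-onset times: spikes preceded by at least ``gap_s`` silence."""
    if spikes.size == 0:
        return spikes
    keep = np.concatenate([[True], np.diff(spikes) > gap_s])
    return spikes[keep]


def run_simulation(
    config: SimConfig,
    network: Network | None = None,
    injured: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Integrate the network for ``t_total`` seconds.

    Separate random streams drive network construction, injury-set
    sampling and the stochastic dynamics, so runs differing only in
    ``injury_fraction`` share wiring and background noise bit-exactly
    (a zero-fraction run is identical to its uninjured control).
    """
    seed_seq = np.random.SeedSequence(config.seed)
    net_ss, inj_ss, dyn_ss = seed_seq.spawn(3)
    if network is None:
        network = build_network(config, np.random.default_rng(net_ss))
    if injured is None:
        injured = apply_injury(config, network, np.random.default_rng(inj_ss))
    if rng is None:
        rng = np.random.default_rng(dyn_ss)

    n = config.n_neurons
    dt_ms = config.dt_s * 1e3
    n_steps = int(round(config.t_total_s / config.dt_s))
    ttx = config.scenario == "ttx"
    g_gaba = 0.0 if config.scenario == "bmb" else config.g_gaba_ns

    def kernel_norm(tr: float, td: float) -> float:
        tpk = np.log(td / tr) * tr * td / (td - tr)
        return np.exp(-tpk / td) - np.exp(-tpk / tr)

    taus = [config.tau_ampa_ms, config.tau_nmda_ms, config.tau_gaba_ms]
    p_peaks = [config.p_peak_ampa, config.p_peak_nmda, config.p_peak_gaba]
    norms = np.array([p / kernel_norm(tr, td) for (tr, td), p in zip(taus, p_peaks)])
    decay_d = np.array([np.exp(-dt_ms / td) for _, td in taus])[:, None]
    decay_r = np.array([np.exp(-dt_ms / tr) for tr, _ in taus])[:, None]

    # aggregated receptor totals per postsynaptic neuron
    spc = config.synapses_per_connection
    in_exc = network.w_exc.sum(axis=1) * spc
    in_inh = network.w_inh.sum(axis=1) * spc
    n_tot = np.stack([
        np.maximum(1, in_exc * config.n_ampa + config.bg_receptors).astype(np.int64),
        np.maximum(1, in_exc * config.n_nmda).astype(np.int64),
        np.maximum(1, in_inh * config.n_gaba).astype(np.int64),
    ])

    a_state = np.zeros((3, n))   # decay-side kernel state
    b_state = np.zeros((3, n))   # rise-side kernel state
    v = np.full(n, config.e_rest_mv)
    ca = np.full(n, config.ca_baseline_mm)
    ca[injured] = config.injury_clamp_mm
    refract = np.zeros(n, dtype=int)
    ref_steps = max(1, int(round(config.refractory_s / config.dt_s)))
    h_lt = np.ones(n)
    is_ib = network.phenotype == "exc_ib"
    is_exc = network.phenotype != "inh"
    spk_prev = np.zeros(n, dtype=bool)

    ions_to_mm = 1e3 / (AVOGADRO * config.cell_volume_pl * 1e-12)
    g_ca_flux = config.g_nmda_ns * 1e-9 / (config.z_ca * config.e_charge_c)
    bg_lam = config.bg_rate_hz * config.dt_s

    v_rec = np.empty((n, n_steps + 1))
    ca_rec = np.empty((n, n_steps + 1))
    v_rec[:, 0] = v
    ca_rec[:, 0] = ca
    spikes: list[list[float]] = [[] for _ in range(n)]
    injury_end = config.injury_duration_s

    for step in range(1, n_steps + 1):
        t = step * config.dt_s
        in_window = t <= injury_end
        a_state *= decay_d
        b_state *= decay_r
        if spk_prev.any():
            live = spk_prev & ~(injured & in_window)
            drive_e = network.w_exc @ (live & is_exc).astype(float) * spc
            drive_i = network.w_inh @ (live & ~is_exc).astype(float) * spc
            a_state[0] += drive_e * config.n_ampa
            b_state[0] += drive_e * config.n_ampa
            a_state[1] += drive_e * config.n_nmda
            b_state[1] += drive_e * config.n_nmda
            a_state[2] += drive_i * config.n_gaba
            b_state[2] += drive_i * config.n_gaba
        bg = rng.poisson(bg_lam, n)
        if bg.any():
            a_state[0] += bg * config.bg_receptors
            b_state[0] += bg * config.bg_receptors

        expected = norms[:, None] * (a_state - b_state)
        p_open = np.clip(expected / n_tot, 0.0, 1.0)
        n_open = rng.binomial(n_tot, p_open)

        p_unb = 1.0 / (1.0 + np.exp(-0.062 * v) * config.mg_mm / 3.57)
        i_syn = (
            -config.g_ampa_ns * (v - config.e_ampa_mv) * n_open[0]
            - config.g_nmda_ns * (v - config.e_nmda_mv) * n_open[1] * p_unb
            - g_gaba * (v - config.e_gaba_mv) * n_open[2]
        )
        i_rest = -config.g_leak_ns * (v - config.e_rest_mv)
        i_kca = -config.g_kca_ns_per_mm * ca * (v - config.e_k_mv)
        m_inf = 1.0 / (1.0 + np.exp(-(v + 60.0) / 6.2))
        h_inf = 1.0 / (1.0 + np.exp((v + 84.0) / 4.0))
        h_lt += config.dt_s / config.tau_h_lt_s * (h_inf - h_lt)
        i_lt = np.where(is_ib, config.g_lt_ns * m_inf**2 * h_lt * (120.0 - v), 0.0)

        try:
            v = membrane_step(v, i_rest + i_kca + i_lt + i_syn,
                              config.dt_s, config.c_m_pf)
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at t={t:.3f}s") from None

        frozen = injured & in_window
        v[frozen] = config.e_rest_mv

        in_refract = refract > 0
        v[in_refract] = config.v_reset_mv
        refract[in_refract] -= 1

        can_spike = ~in_refract & ~frozen
        spk = (v >= config.v_threshold_mv) & can_spike
        if ttx:
            spk[:] = False
        if spk.any():
            for i in np.nonzero(spk)[0]:
                spikes[i].append(t)
            v_out = v.copy()
            v_out[spk] = config.v_spike_mv
            v[spk] = config.v_reset_mv
            refract[spk] = ref_steps
        else:
            v_out = v

        # calcium passes only the unblocked fraction of open NMDA channels
        ions = g_ca_flux * np.abs(v) * 1e-3 * n_open[1] * p_unb * config.dt_s
        free = (1.0 - config.buffer_fraction) * ions
        ca = ca + free * ions_to_mm - config.dt_s / config.tau_ca_s * (
            ca - config.ca_baseline_mm
        )
        ca = ca + spk * config.ca_per_spike_mm
        ca = np.maximum(ca, 0.0)
        ca[frozen] = config.injury_clamp_mm

        v_rec[:, step] = v_out
        ca_rec[:, step] = ca
        spk_prev = spk

    spike_trains = [np.asarray(s) for s in spikes]
    event_trains = [_events_from_spikes(s) for s in spike_trains]
    return SimResult(
        config=config, network=network,
        spike_trains=spike_trains, event_trains=event_trains,
        v_traces=v_rec, ca_traces=ca_rec,
        time=np.arange(n_steps + 1) * config.dt_s,
        injured=injured, seed=config.seed,
    )


def _si_field_of_view(
    trains: list[np.ndarray],
    duration: float,
    n_surrogates: int,
    rng: np.random.Generator,
    fs: float = 10.0,
) -> float:
    """Global SI over the whole field, silent cells counted as unsynchronized.

    A neuron that produced no events contributes a zero row to the sync
    matrix (it coordinates with nobody), matching how a dropped-out cell
    enters the imaging analysis.  Pairs of active neurons use the usual
    phase-difference average.
    """
    sts = SpikeTrainSet(trains=trains, duration=duration)
    phases, _ = phase_series(sts, fs)
    s = _sync_from_phases(phases, fs)
    s = np.where(np.isnan(s), 0.0, s)
    np.fill_diagonal(s, 1.0)
    surr = []
    for _ in range(n_surrogates):
        sp = np.full_like(phases, np.nan)
        for i in range(phases.shape[0]):
            valid = ~np.isnan(phases[i])
            if valid.sum() >= 8:
                from .netmetrics import aaft_surrogate
                sp[i, valid] = aaft_surrogate(phases[i, valid], rng)
        ss = _sync_from_phases(sp, fs)
        ss = np.where(np.isnan(ss), 0.0, ss)
        np.fill_diagonal(ss, 1.0)
        surr.append(ss)
    _, _, si = sync_indices(s, surr)
    return si


def _amplitude(ca_traces: np.ndarray) -> np.ndarray:
    """Oscillation amplitude per neuron: 5th-95th percentile calcium span."""
    return np.percentile(ca_traces, 95, axis=1) - np.percentile(ca_traces, 5, axis=1)


def injury_experiment(
    config: SimConfig,
    n_surrogates: int = 50,
    alpha: float = 0.05,
    pre: SimResult | None = None,
) -> dict:
    """Matched pre/post injury comparison for one seed.

    Runs the uninjured network and the injured network with identical
    wiring and noise, then reports the synchronization-index ratio
    (SI_post/SI_pre), connectivity-index ratio (mean CI over the whole
    field), and the calcium-oscillation amplitude ratio of the cells
    that were left uninjured.  A precomputed uninjured run (same seed)
    can be passed to avoid repeating it across fractions.
    """
    if pre is None:
        pre = run_simulation(replace(config, injury_fraction=0.0))
    post = run_simulation(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed or 0) + 7))

    duration = config.t_total_s
    si_pre = _si_field_of_view(pre.event_trains, duration, n_surrogates, rng)
    si_post = _si_field_of_view(post.event_trains, duration, n_surrogates, rng)

    def mean_ci(res: SimResult) -> float:
        sts = SpikeTrainSet(trains=res.event_trains, duration=duration)
        _, ci = connectivity(sts, n_surrogates=min(n_surrogates, 39), rng=rng)
        return float(np.mean(ci))

    ci_pre = mean_ci(pre)
    ci_post = mean_ci(post)

    uninjured = ~post.injured
    amp_pre = _amplitude(pre.ca_traces[uninjured])
    amp_post = _amplitude(post.ca_traces[uninjured])
    amp_ratio = float(np.mean(amp_post) / np.mean(amp_pre)) if np.mean(amp_pre) > 0 else float("nan")

    return {
        "injury_fraction": config.injury_fraction,
        "seed": config.seed,
        "si_pre": si_pre, "si_post": si_post,
        "si_ratio": si_post / si_pre if si_pre > 0 else float("nan"),
        "ci_pre": ci_pre, "ci_post": ci_post,
        "ci_ratio": ci_post / ci_pre if ci_pre > 0 else float("nan"),
        "amp_ratio": amp_ratio,
        "n_injured": int(post.injured.sum()),
    }


def injury_sweep(
    base_config: SimConfig,
    fractions: tuple[float, ...] = (0.0, 0.13, 0.25, 0.50, 0.75),
    seeds: tuple[int, ...] = tuple(range(10)),
    n_surrogates: int = 50,
) -> list[dict]:
    """Injury-fraction sweep across seeds (the in-silico dose response)."""
    rows = []
    for seed in seeds:
        pre = run_simulation(replace(base_config, injury_fraction=0.0, seed=seed))
        for f in fractions:
            cfg = replace(base_config, injury_fraction=f, seed=seed)
            rows.append(injury_experiment(cfg, n_surrogates=n_surrogates, pre=pre))
    return rows
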