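"""Synthetic data generators for the injury-analysis pipeline.

Everything downstream of image acquisition — transient detection,
synchronization metrics, fate modeling, micro-post calibration — can be
exercised on data built here, with ground truth attached.  The
generators emulate:

* 10 Hz GCaMP-like somatic fluorescence of 20-100 cultured cortical
  neurons whose population oscillates around 0.35 Hz with a tunable
  degree of synchrony,
* graded micromechanical-injury signatures: primary calcium rises
  (latency < 0.5 s), secondary rises (0.5-5 s, more likely with
  distance from the epicenter), and rare membrane poration in which the
  cytosolic indicator collapses toward zero,
* binary 6-hour live/dead outcomes drawn from a known logistic model on
  the eight per-cell predictors, and
* hexagonal micro-post (mPAD) centroid tables displaced by a known
  force field.

The synchrony model is a common-mother Poisson process: a mother train
at the population rate is thinned per neuron with probability
``sync_level`` and topped up with an independent Poisson train at rate
``(1 - sync_level) * base_rate``, then jittered.  ``sync_level`` is the
[0, 1] dial spanning independent firing to identical trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmetrics import SpikeTrainSet

__all__ = [
    "SynthNetworkSpec",
    "InjurySignatureSpec",
    "FateModelSpec",
    "GroundTruth",
    "CALCIUM_KERNEL_RISE_S",
    "CALCIUM_KERNEL_DECAY_S",
    "calcium_kernel",
    "generate_spike_trains",
    "spikes_to_fluorescence",
    "CalciumTraceSet",
    "inject_injury_signatures",
    "generate_feature_records",
    "generate_fate_labels",
    "generate_mpad_table",
]

#: GCaMP-like transient kernel constants (difference of exponentials)
CALCIUM_KERNEL_RISE_S = 0.1
CALCIUM_KERNEL_DECAY_S = 1.0

#: dwell time of the injury calcium plateau before return to baseline, s
INJURY_PLATEAU_S = 30.0

#: fluorescence collapse time constant for porated cells, s
PORATION_DECAY_S = 1.0

FEATURE_NAMES = ["pi_pre", "ci_pre", "r_pre", "pi_post", "ci_post", "r_post", "s", "d"]


@dataclass
class SynthNetworkSpec:
    """Parameters of a synthetic cultured network recording.

    ``base_rate`` defaults to the 0.35 Hz population-oscillation rate of
    mature control cultures; ``frame_rate`` to the 10 Hz stream
    acquisition of the imaging rig being emulated.
    """

    n_neurons: int = 20
    field_size: float = 455.0          # um, square side (imaging field of view)
    frame_rate: float = 10.0           # Hz
    duration: float = 60.0             # s
    base_rate: float = 0.35            # Hz
    sync_level: float = 0.8
    jitter_sd: float = 0.05            # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.frame_rate <= 0 or self.duration <= 0 or self.base_rate <= 0:
            raise ValueError("frame_rate, duration and base_rate must be positive")
        if not 0.0 <= self.sync_level <= 1.0:
            raise ValueError("sync_level must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


@dataclass
class InjurySignatureSpec:
    """Shape of the micromechanical-injury response painted onto traces.

    Peak amplitudes interpolate from ``peak_near`` (percent above
    baseline within 100 um of the epicenter, default 291) down to
    ``peak_far`` (beyond 400 um, default 143) with distance; primary
    responses peak in under 0.5 s while secondary responses lag 0.5-5 s
    with probability increasing away from the epicenter.  A small
    ``poration_fraction`` of cells instead lose their indicator entirely.
    """

    epicenter: tuple[float, float] = (227.5, 227.5)   # um
    injured_fraction: float = 0.5
    primary_latency_max: float = 0.5                  # s
    secondary_latency_range: tuple[float, float] = (0.5, 5.0)
    poration_fraction: float = 0.03
    peak_near: float = 291.0                          # percent over baseline, d <= 100 um
    peak_far: float = 143.0                           # percent over baseline, d > 400 um
    stimulus_time: float = 20.0                       # s

    def __post_init__(self) -> None:
        for name in ("injured_fraction", "poration_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.injured_fraction + self.poration_fraction > 1.0:
            raise ValueError("injured and porated fractions sum beyond 1")
        if self.peak_near < self.peak_far:
            raise ValueError("peak_near must be >= peak_far")
        if self.primary_latency_max <= 0 or self.secondary_latency_range[0] <= 0:
            raise ValueError("latencies must be positive")


@dataclass
class FateModelSpec:
    """Known logistic model generating binary live/dead outcomes.

    ``coefficients`` holds one log-odds slope per predictor in
    ``FEATURE_NAMES`` order (pi_pre, ci_pre, r_pre, pi_post, ci_post,
    r_post, severity, distance).  A positive severity slope and a
    negative distance slope reproduce the qualitative pattern that death
    rises with injury grade and falls with distance from the epicenter.
    """

    intercept: float = -1.0
    coefficients: np.ndarray = field(
        default_factory=lambda: np.array([-0.5, -0.5, -0.8, -1.5, -1.0, -1.2, 0.9, -0.004])
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(FEATURE_NAMES):
            raise ValueError(f"need {len(FEATURE_NAMES)} coefficients")

    def death_probability(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("features must be finite")
        logit = self.intercept + x @ self.coefficients
        return 1.0 / (1.0 + np.exp(-logit))


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests."""

    spike_times: list[np.ndarray] | None = None
    positions: np.ndarray | None = None              # (M, 2) um
    response_class: list[str] | None = None          # primary/secondary/poration/none
    response_latency: np.ndarray | None = None       # s, NaN for non-responders
    response_peak_pct: np.ndarray | None = None      # percent over baseline
    fate: np.ndarray | None = None                   # 1 = dead
    features: pd.DataFrame | None = None
    seed: int | None = None


@dataclass
class CalciumTraceSet:
    """Sampled fluorescence matrix with acquisition metadata."""

    traces: np.ndarray                               # (M, T)
    time: np.ndarray                                 # (T,) s
    positions: np.ndarray                            # (M, 2) um
    frame_rate: float
    f0: float = 100.0
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.frame_rate


def calcium_kernel(
    t: np.ndarray,
    rise: float = CALCIUM_KERNEL_RISE_S,
    decay: float = CALCIUM_KERNEL_DECAY_S,
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient kernel."""
    if rise <= 0 or decay <= rise:
        raise ValueError("need 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    tpk = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    out = (np.exp(-t / decay) - np.exp(-t / rise)) / peak
    return np.where(t >= 0, out, 0.0)


def kernel_peak_delay(
    rise: float = CALCIUM_KERNEL_RISE_S, decay: float = CALCIUM_KERNEL_DECAY_S
) -> float:
    """Delay from event onset to kernel peak (used to align detections)."""
    return float(np.log(decay / rise) * rise * decay / (decay - rise))


def generate_spike_trains(
    spec: SynthNetworkSpec,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Draw per-neuron event trains with a tunable population synchrony.

    At ``sync_level=1`` with zero jitter every neuron fires the shared
    mother train exactly; at ``sync_level=0`` the trains are independent
    Poisson at ``base_rate``.  Each neuron's expected rate is
    ``base_rate`` regardless of the synchrony setting.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.duration * spec.base_rate < 1.0:
        raise ValueError(
            "duration too short: fewer than one expected event per neuron"
        )
    n_mother = rng.poisson(spec.base_rate * spec.duration)
    mother = np.sort(rng.uniform(0.0, spec.duration, n_mother))
    trains = []
    for _ in range(spec.n_neurons):
        if spec.sync_level >= 1.0:
            shared = mother.copy()
        else:
            shared = mother[rng.random(mother.size) < spec.sync_level]
        indep_rate = (1.0 - spec.sync_level) * spec.base_rate
        n_ind = rng.poisson(indep_rate * spec.duration)
        indep = rng.uniform(0.0, spec.duration, n_ind)
        t = np.concatenate([shared, indep])
        if spec.jitter_sd > 0:
            t = t + rng.normal(0.0, spec.jitter_sd, t.size)
        t = np.sort(t[(t >= 0) & (t <= spec.duration)])
        # enforce strictly increasing times (jitter can create ties)
        t = np.unique(t)
        trains.append(t)
    positions = rng.uniform(0.0, spec.field_size, (spec.n_neurons, 2))
    truth = GroundTruth(spike_times=[t.copy() for t in trains],
                        positions=positions, seed=spec.seed)
    return SpikeTrainSet(trains=trains, duration=spec.duration), truth


def spikes_to_fluorescence(
    trains: SpikeTrainSet,
    spec: SynthNetworkSpec,
    amplitude: float = 0.5,
    noise_sd: float = 0.0,
    f0: float = 100.0,
    rise: float = CALCIUM_KERNEL_RISE_S,
    decay: float = CALCIUM_KERNEL_DECAY_S,
    positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> CalciumTraceSet:
    """Forward model from events to sampled fluorescence.

    ``F(t) = F0 * (1 + amplitude * sum_k kernel(t - t_k)) + noise`` with
    additive Gaussian noise of standard deviation ``noise_sd`` (in
    fluorescence units).  A train with no events yields baseline plus
    noise only.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    tgrid = np.arange(0.0, trains.duration, 1.0 / spec.frame_rate)
    out = np.empty((trains.n_neurons, tgrid.size))
    for i, tr in enumerate(trains.trains):
        signal = np.zeros_like(tgrid)
        for s in tr:
            signal += calcium_kernel(tgrid - s, rise, decay)
        out[i] = f0 * (1.0 + amplitude * signal)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    if positions is None:
        positions = rng.uniform(0.0, spec.field_size, (trains.n_neurons, 2))
    return CalciumTraceSet(
        traces=out, time=tgrid, positions=positions,
        frame_rate=spec.frame_rate, f0=f0, seed=spec.seed,
    )


def inject_injury_signatures(
    traces: CalciumTraceSet,
    isp: InjurySignatureSpec,
    rng: np.random.Generator | int | None = None,
    plateau_s: float = INJURY_PLATEAU_S,
) -> tuple[CalciumTraceSet, GroundTruth]:
    """Paint injury responses onto a copy of the trace set.

    Injured cells receive a sustained calcium plateau whose peak
    amplitude interpolates from ``peak_near`` percent over baseline near
    the epicenter down to ``peak_far`` beyond 400 um.  Latency is drawn
    below ``primary_latency_max`` for cells assigned a primary response
    and inside ``secondary_latency_range`` otherwise, with the secondary
    probability rising with distance.  Porated cells' fluorescence
    decays exponentially toward zero.  Uninvolved cells are untouched.
    """
    rng = np.random.default_rng(rng)
    m = traces.n_neurons
    ex, ey = isp.epicenter
    d = np.hypot(traces.positions[:, 0] - ex, traces.positions[:, 1] - ey)
    n_por = int(round(isp.poration_fraction * m))
    n_inj = int(round(isp.injured_fraction * m))
    # nearer cells are the likelier injury targets
    order = np.argsort(d + rng.normal(0.0, 50.0, m))
    porated = order[:n_por]
    injured = order[n_por:n_por + n_inj]

    out = traces.traces.copy()
    t = traces.time
    classes = ["none"] * m
    latency = np.full(m, np.nan)
    peak_pct = np.full(m, np.nan)

    for i in injured:
        # secondary response more likely with distance from the epicenter
        p_secondary = np.clip(d[i] / 400.0, 0.05, 0.95)
        if rng.random() < p_secondary:
            lo, hi = isp.secondary_latency_range
            lat = rng.uniform(lo, hi)
            classes[i] = "secondary"
        else:
            lat = rng.uniform(0.05, isp.primary_latency_max * 0.9)
            classes[i] = "primary"
        frac = np.clip((d[i] - 100.0) / 300.0, 0.0, 1.0)
        pct = isp.peak_near + frac * (isp.peak_far - isp.peak_near)
        latency[i] = lat
        peak_pct[i] = pct
        onset = isp.stimulus_time + lat
        rel = t - onset
        ramp_tau = 0.1 if classes[i] == "primary" else 0.5
        plateau = np.where(
            rel < 0, 0.0,
            np.where(rel < plateau_s, 1.0 - np.exp(-rel / ramp_tau),
                     np.exp(-(rel - plateau_s) / 5.0)),
        )
        out[i] = out[i] + traces.f0 * (pct / 100.0) * plateau
    for i in porated:
        classes[i] = "poration"
        rel = t - isp.stimulus_time
        decay = np.where(rel < 0, 1.0, np.exp(-rel / PORATION_DECAY_S))
        out[i] = out[i] * decay

    truth = GroundTruth(
        positions=traces.positions,
        response_class=classes,
        response_latency=latency,
        response_peak_pct=peak_pct,
        seed=traces.seed,
    )
    new = CalciumTraceSet(
        traces=out, time=t.copy(), positions=traces.positions.copy(),
        frame_rate=traces.frame_rate, f0=traces.f0, seed=traces.seed,
    )
    return new, truth


def generate_feature_records(
    n: int, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Plausible per-cell predictor table for fate-model calibration.

    Participation and connectivity indices are Beta-distributed in
    [0, 1] (post-injury values shrunk toward 0), event rates are
    lognormal around the 0.35 Hz baseline, severity is an ordinal grade
    0-3 (D..A) and distance is uniform over the imaged field.
    """
    rng = np.random.default_rng(rng)
    pi_pre = rng.beta(4.0, 2.0, n)
    ci_pre = rng.beta(4.0, 2.0, n)
    r_pre = rng.lognormal(np.log(0.35), 0.3, n)
    # each metric degrades by its own factor: cells lose participation,
    # connections and rate to different degrees
    pi_post = pi_pre * rng.beta(2.0, 2.0, n)
    ci_post = ci_pre * rng.beta(2.0, 2.0, n)
    r_post = r_pre * rng.beta(2.0, 2.0, n)
    severity = rng.integers(0, 4, n).astype(float)
    distance = rng.uniform(0.0, 600.0, n)
    return pd.DataFrame(
        {
            "pi_pre": pi_pre, "ci_pre": ci_pre, "r_pre": r_pre,
            "pi_post": pi_post, "ci_post": ci_post, "r_post": r_post,
            "s": severity, "d": distance,
        }
    )


def generate_fate_labels(
    features: pd.DataFrame | np.ndarray, fm: FateModelSpec,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Bernoulli live/dead draws from the logistic fate model (1 = dead)."""
    if rng is None:
        rng = np.random.default_rng(fm.seed)
    else:
        rng = np.random.default_rng(rng)
    if isinstance(features, pd.DataFrame):
        x = features[FEATURE_NAMES].to_numpy()
    else:
        x = np.atleast_2d(features)
    p = fm.death_probability(x)
    return (rng.random(p.size) < p).astype(int)


def generate_mpad_table(
    n_posts: int = 61,
    pitch: float = 4.0,
    true_forces: np.ndarray | None = None,
    force_angles: np.ndarray | None = None,
    k: float = 7.22,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hexagonal micro-post centroid table before/during a pressure pulse.

    Posts sit on a close-packed hexagonal grid with the given pitch
    (default 4 um).  During the pulse each post is displaced by
    ``F / k`` along its force angle plus isotropic localization noise.
    Returns ``(table, truth)`` where the table holds matched
    before/during centroids and truth the per-post force magnitudes.
    """
    rng = np.random.default_rng(rng)
    # build hexagonal rings around a central post until n_posts reached
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n_posts:
        for i in range(6 * ring):
            side, step = divmod(i, ring)
            ang = np.pi / 3.0 * side
            bx, by = ring * pitch * np.cos(ang), ring * pitch * np.sin(ang)
            dx = step * pitch * np.cos(ang + 2.0 * np.pi / 3.0)
            dy = step * pitch * np.sin(ang + 2.0 * np.pi / 3.0)
            pts.append((bx + dx, by + dy))
        ring += 1
    before = np.array(pts[:n_posts])
    if true_forces is None:
        true_forces = np.zeros(n_posts)
    true_forces = np.asarray(true_forces, dtype=float)
    if not np.all(np.isfinite(true_forces)):
        raise ValueError("forces must be finite")
    if force_angles is None:
        force_angles = np.zeros(n_posts)
    disp = (true_forces / k)[:, None] * np.column_stack(
        [np.cos(force_angles), np.sin(force_angles)]
    )
    during = before + disp
    if noise_sd > 0:
        during = during + rng.normal(0.0, noise_sd, during.shape)
    table = pd.DataFrame(
        {
            "post_id": np.arange(n_posts),
            "x_before": before[:, 0], "y_before": before[:, 1],
            "x_during": during[:, 0], "y_during": during[:, 1],
        }
    )
    truth = pd.DataFrame(
        {"post_id": np.arange(n_posts), "force_nN": true_forces,
         "angle_rad": np.broadcast_to(force_angles, (n_posts,))}
    )
    return table, truth
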