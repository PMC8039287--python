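"""Synthetic-data generator contracts and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from microtrauma.synth import (
    CalciumTraceSet,
    FateModelSpec,
    InjurySignatureSpec,
    SynthNetworkSpec,
    calcium_kernel,
    generate_fate_labels,
    generate_feature_records,
    generate_mpad_table,
    generate_spike_trains,
    inject_injury_signatures,
    spikes_to_fluorescence,
)


class TestSpikeTrains:
    def test_full_sync_zero_jitter_identical_trains(self):
        spec = SynthNetworkSpec(n_neurons=20, sync_level=1.0, jitter_sd=0.0,
                                duration=120.0, seed=7)
        trains, truth = generate_spike_trains(spec)
        for t in trains.trains[1:]:
            assert np.array_equal(t, trains.trains[0])

    def test_rate_matches_baseline_within_3_se(self):
        spec = SynthNetworkSpec(n_neurons=30, duration=600.0, base_rate=0.35,
                                sync_level=0.5, seed=11)
        trains, _ = generate_spike_trains(spec)
        rate = trains.rates().mean()
        # SE of the grand mean rate over 30 x 600 s of (correlated) events
        se = np.sqrt(0.35 / 600.0)
        assert abs(rate - 0.35) < 3 * se

    def test_zero_sync_pairs_rarely_significant(self):
        from microtrauma.netmetrics import connectivity
        n_edges = 0
        n_runs = 40
        for seed in range(n_runs):
            spec = SynthNetworkSpec(n_neurons=2, duration=120.0, sync_level=0.0,
                                    seed=seed)
            trains, _ = generate_spike_trains(spec)
            if min(len(t) for t in trains.trains) < 2:
                continue
            edges, _ = connectivity(trains, n_surrogates=39, alpha=0.05, rng=seed)
            n_edges += len(edges)
        assert n_edges / n_runs <= 0.2

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration too short"):
            generate_spike_trains(
                SynthNetworkSpec(n_neurons=3, duration=1.0, base_rate=0.35, seed=0)
            )

    def test_trains_strictly_increasing_inside_window(self):
        spec = SynthNetworkSpec(n_neurons=10, duration=60.0, sync_level=0.7,
                                jitter_sd=0.1, seed=3)
        trains, _ = generate_spike_trains(spec)
        for t in trains.trains:
            assert np.all(np.diff(t) > 0)
            if t.size:
                assert t[0] >= 0 and t[-1] <= 60.0


class TestFluorescence:
    def test_empty_train_constant_baseline(self):
        spec = SynthNetworkSpec(n_neurons=2, duration=10.0, seed=0)
        from microtrauma.netmetrics import SpikeTrainSet
        trains = SpikeTrainSet([np.array([]), np.array([])], 10.0)
        traces = spikes_to_fluorescence(trains, spec, noise_sd=0.0, f0=100.0)
        assert np.allclose(traces.traces, 100.0)

    def test_single_spike_peak_amplitude(self):
        spec = SynthNetworkSpec(n_neurons=2, duration=10.0, seed=0)
        from microtrauma.netmetrics import SpikeTrainSet
        trains = SpikeTrainSet([np.array([2.0]), np.array([])], 10.0)
        traces = spikes_to_fluorescence(trains, spec, amplitude=0.5,
                                        noise_sd=0.0, f0=100.0)
        # sampled trace equals F0*(1 + A*kernel) exactly at the frames
        tgrid = traces.time
        expected = 100.0 * (1.0 + 0.5 * calcium_kernel(tgrid - 2.0))
        assert np.allclose(traces.traces[0], expected)
        assert traces.traces[0].max() == pytest.approx(150.0, rel=0.02)

    def test_frame_interval_is_tenth_second(self):
        spec = SynthNetworkSpec(n_neurons=2, duration=5.0, seed=0)
        trains, _ = generate_spike_trains(
            SynthNetworkSpec(n_neurons=2, duration=5.0, base_rate=1.0, seed=0)
        )
        traces = spikes_to_fluorescence(trains, spec)
        assert np.allclose(np.diff(traces.time), 0.1)


def _flat_traces(n=20, duration=60.0, f0=100.0, field=455.0, seed=0):
    rng = np.random.default_rng(seed)
    tgrid = np.arange(0.0, duration, 0.1)
    return CalciumTraceSet(
        traces=np.full((n, tgrid.size), f0),
        time=tgrid,
        positions=rng.uniform(0, field, (n, 2)),
        frame_rate=10.0,
        f0=f0,
    )


class TestInjurySignatures:
    def test_no_injury_leaves_traces_unchanged(self):
        traces = _flat_traces()
        isp = InjurySignatureSpec(injured_fraction=0.0, poration_fraction=0.0)
        out, truth = inject_injury_signatures(traces, isp, rng=1)
        assert np.array_equal(out.traces, traces.traces)
        assert all(c == "none" for c in truth.response_class)

    def test_near_epicenter_peak_is_291_percent(self):
        traces = _flat_traces(n=10)
        traces.positions[0] = (227.5 + 50.0, 227.5)  # 50 um from epicenter
        isp = InjurySignatureSpec(injured_fraction=1.0, poration_fraction=0.0)
        out, truth = inject_injury_signatures(traces, isp, rng=2)
        assert truth.response_peak_pct[0] == pytest.approx(291.0)
        # plateau reaches the nominal amplitude before it decays
        assert out.traces[0].max() == pytest.approx(100.0 * 3.91, rel=0.01)

    def test_peak_amplitude_decreases_with_distance(self):
        traces = _flat_traces(n=12, field=900.0)
        isp = InjurySignatureSpec(epicenter=(0.0, 0.0), injured_fraction=1.0,
                                  poration_fraction=0.0)
        out, truth = inject_injury_signatures(traces, isp, rng=3)
        d = np.hypot(*traces.positions.T)
        order = np.argsort(d)
        peaks = truth.response_peak_pct[order]
        assert np.all(np.diff(peaks) <= 1e-9)
        assert peaks[0] >= peaks[-1]

    def test_poration_collapses_fluorescence(self):
        traces = _flat_traces(n=10)
        isp = InjurySignatureSpec(injured_fraction=0.0, poration_fraction=0.2,
                                  stimulus_time=20.0)
        out, truth = inject_injury_signatures(traces, isp, rng=4)
        porated = [i for i, c in enumerate(truth.response_class) if c == "poration"]
        assert len(porated) == 2
        final = out.traces[porated][:, -50:]  # last 5 s
        assert np.all(final.mean(axis=1) < 0.1 * traces.f0)

    def test_fraction_overflow_rejected(self):
        with pytest.raises(ValueError):
            InjurySignatureSpec(injured_fraction=0.9, poration_fraction=0.2)

    def test_latency_classes_respect_cutoffs(self):
        traces = _flat_traces(n=30)
        isp = InjurySignatureSpec(injured_fraction=1.0, poration_fraction=0.0)
        _, truth = inject_injury_signatures(traces, isp, rng=5)
        for cls, lat in zip(truth.response_class, truth.response_latency):
            if cls == "primary":
                assert lat < 0.5
            elif cls == "secondary":
                assert 0.5 <= lat <= 5.0


class TestFateModel:
    def test_null_model_death_rate_half(self):
        fm = FateModelSpec(intercept=0.0, coefficients=np.zeros(8), seed=0)
        x = generate_feature_records(10_000, rng=1)
        labels = generate_fate_labels(x, fm, rng=2)
        assert abs(labels.mean() - 0.5) < 0.02

    def test_death_rate_decreases_with_distance(self):
        fm = FateModelSpec(seed=0)  # default beta_d < 0
        x = generate_feature_records(20_000, rng=3)
        labels = generate_fate_labels(x, fm, rng=4)
        bins = pd.cut(x["d"], [0, 200, 400, 600])
        rates = pd.Series(labels).groupby(bins, observed=True).mean()
        assert rates.is_monotonic_decreasing

    def test_probability_monotone_in_severity(self):
        fm = FateModelSpec(seed=0)  # beta_s > 0
        base = generate_feature_records(1, rng=5).iloc[0].to_numpy()
        probs = []
        for s in range(4):
            row = base.copy()
            row[6] = s
            probs.append(float(fm.death_probability(row)[0]))
        assert np.all(np.diff(probs) > 0)

    def test_coefficient_recovery_from_5000_records(self):
        import statsmodels.api as sm
        fm = FateModelSpec(seed=0)
        x = generate_feature_records(5000, rng=6)
        y = generate_fate_labels(x, fm, rng=7)
        design = sm.add_constant(x)
        res = sm.Logit(y, design).fit(disp=False)
        ci = res.conf_int(alpha=0.05)
        truth = np.concatenate([[fm.intercept], fm.coefficients])
        inside = [(lo <= b <= hi) for b, (lo, hi) in zip(truth, ci.to_numpy())]
        assert sum(inside) >= 8  # of 9 parameters


class TestMpadTable:
    def test_zero_forces_identity(self):
        table, _ = generate_mpad_table(n_posts=19, noise_sd=0.0)
        assert np.allclose(table[["x_before", "y_before"]].to_numpy(),
                           table[["x_during", "y_during"]].to_numpy())

    def test_known_force_gives_known_displacement(self):
        forces = np.zeros(19)
        forces[0] = 0.722
        table, _ = generate_mpad_table(n_posts=19, true_forces=forces,
                                       k=7.22, noise_sd=0.0)
        dx = table["x_during"] - table["x_before"]
        dy = table["y_during"] - table["y_before"]
        disp = np.hypot(dx, dy)
        assert disp[0] == pytest.approx(0.100, abs=1e-12)
        assert np.allclose(disp[1:], 0.0)

    def test_hexagonal_pitch_is_4_um(self):
        from scipy.spatial import cKDTree
        table, _ = generate_mpad_table(n_posts=37, noise_sd=0.0)
        pts = table[["x_before", "y_before"]].to_numpy()
        dist, _ = cKDTree(pts).query(pts, k=2)
        assert np.allclose(dist[:, 1], 4.0, atol=1e-9)
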