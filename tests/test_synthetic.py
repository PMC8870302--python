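"""Tests of the MVAR generator: determinism, stationarity guards, spectral
placement, and recoverability of the built-in causal ground truth."""

import numpy as np
import pytest
from scipy import signal

from braingc.granger import gci_pair
from braingc.recording import Recording
from braingc.synthetic import (
    CouplingGraph,
    MVARSpec,
    ScenarioSpec,
    StateSpec,
    band_peaked_ar_coeffs,
    default_scenario,
    generate_mvar,
    generate_scenario,
    multi_peak_ar_coeffs,
    scale_edges_incident,
)

from conftest import two_node_spec


class TestCouplingGraph:
    def test_rejects_self_loops_and_bad_nodes(self):
        with pytest.raises(ValueError, match="self-loop"):
            CouplingGraph(2, ((0, 0),), (0.5,), ("a", "b"))
        with pytest.raises(ValueError, match="invalid node"):
            CouplingGraph(2, ((0, 5),), (0.5,), ("a", "b"))
        with pytest.raises(ValueError, match="finite"):
            CouplingGraph(2, ((0, 1),), (float("inf"),), ("a", "b"))

    def test_coupling_matrix_orientation(self):
        g = CouplingGraph(3, ((0, 2),), (0.7,), ("a", "b", "c"))
        w = g.coupling_matrix()
        assert w[2, 0] == 0.7  # target row, source column
        assert w.sum() == 0.7


class TestGenerateMvar:
    def test_fixed_seed_is_bit_identical(self):
        spec = two_node_spec(0.4, seed=42)
        r1 = generate_mvar(spec, 3000)
        r2 = generate_mvar(spec, 3000)
        assert np.array_equal(r1.data, r2.data)

    def test_nonstationary_spec_rejected_with_radius(self):
        g = CouplingGraph(1, (), (), ("a",))
        bad = MVARSpec(g, ((1.05,),), (1.0,), 1000.0, 0)
        with pytest.raises(ValueError, match="spectral radius"):
            generate_mvar(bad, 5000)

    def test_too_few_samples_rejected(self):
        spec = two_node_spec(0.0, seed=1)
        with pytest.raises(ValueError, match="exceed"):
            generate_mvar(spec, 10)

    def test_zero_coupling_gives_near_zero_gci(self):
        rec = generate_mvar(two_node_spec(0.0, seed=7), 5000)
        a, b = gci_pair(rec.data[0], rec.data[1], 2)
        assert a < 0.01 and b < 0.01

    def test_coupled_gci_matches_monte_carlo_oracle(self):
        """A single estimate should sit within 3 SD of the distribution of
        independent re-simulations of the same process."""
        est, _ = gci_pair(*generate_mvar(two_node_spec(0.5, seed=123), 5000).data, 1)
        replicates = np.array(
            [
                gci_pair(*generate_mvar(two_node_spec(0.5, seed=1000 + k), 5000).data, 1)[0]
                for k in range(100)
            ]
        )
        assert abs(est - replicates.mean()) < 3 * replicates.std()
        assert replicates.mean() > 0.05  # coupling clearly detected

    def test_direction_dominates_reverse(self):
        rec = generate_mvar(two_node_spec(0.5, seed=5), 20000)
        fwd, rev = gci_pair(rec.data[0], rec.data[1], 1)
        assert fwd > rev

    def test_weight_scaling_is_monotone_in_median_gci(self):
        medians = []
        for w in (0.6, 0.3, 0.0):
            vals = [
                gci_pair(*generate_mvar(two_node_spec(w, seed=300 + k), 5000).data, 1)[0]
                for k in range(11)
            ]
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]


class TestBandPeakedCoeffs:
    @pytest.mark.parametrize(
        "center,band", [(10.0, (8.0, 13.0)), (20.0, (13.0, 30.0))]
    )
    def test_periodogram_peak_lands_in_band(self, center, band):
        fs = 1000.0
        a1, a2 = band_peaked_ar_coeffs(center, fs)
        g = CouplingGraph(1, (), (), ("a",))
        spec = MVARSpec(g, ((a1, a2),), (1.0,), fs, seed=11)
        rec = generate_mvar(spec, 200_000)
        freqs, psd = signal.welch(rec.data[0], fs=fs, nperseg=4096)
        peak = freqs[np.argmax(psd)]
        assert band[0] <= peak <= band[1]

    def test_center_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_peaked_ar_coeffs(600.0, 1000.0)

    def test_multi_peak_process_is_stationary_with_both_peaks(self):
        fs = 1000.0
        coeffs = multi_peak_ar_coeffs((10.0, 20.0), fs)
        g = CouplingGraph(1, (), (), ("a",))
        spec = MVARSpec(g, (coeffs,), (1.0,), fs, seed=3)
        assert spec.spectral_radius() < 1
        rec = generate_mvar(spec, 60000)
        freqs, psd = signal.welch(rec.data[0], fs=fs, nperseg=8192)
        mu_power = psd[(freqs >= 8) & (freqs < 13)].max()
        beta_power = psd[(freqs >= 13) & (freqs <= 30)].max()
        background = np.median(psd[(freqs > 40) & (freqs < 100)])
        assert mu_power > 10 * background and beta_power > 10 * background


class TestScenario:
    def test_empty_modification_gives_single_rest_recording(self):
        spec = ScenarioSpec(two_node_spec(0.4, seed=2), (StateSpec("rest", 3.0),))
        out = generate_scenario(spec)
        assert len(out) == 1
        name, rec = out[0]
        assert name == "rest" and isinstance(rec, Recording)
        assert rec.n_samples == 3000

    def test_zero_duration_rejected(self):
        spec = ScenarioSpec(
            two_node_spec(0.4, seed=2),
            (StateSpec("rest", 3.0), StateSpec("task", 0.0)),
        )
        with pytest.raises(ValueError, match="duration"):
            generate_scenario(spec)

    def test_duplicate_state_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ScenarioSpec(
                two_node_spec(0.4, seed=2),
                (StateSpec("rest", 3.0), StateSpec("rest", 3.0)),
            )

    def test_states_are_deterministic_and_distinct(self):
        sc = default_scenario(duration_s=5.0, seed=9)
        out1 = generate_scenario(sc)
        out2 = generate_scenario(sc)
        for (n1, r1), (n2, r2) in zip(out1, out2):
            assert n1 == n2 and np.array_equal(r1.data, r2.data)
        assert not np.array_equal(out1[0][1].data, out1[1][1].data)

    def test_every_emitted_state_is_stationary(self):
        sc = default_scenario(duration_s=5.0, seed=9)
        assert sc.base.spectral_radius() < 1
        # Task/post modifications only shrink weights; re-check explicitly.
        from braingc.synthetic import _modified_spec, derive_seed

        for k, st in enumerate(sc.states):
            m = _modified_spec(sc.base, st, derive_seed(sc.base.seed, k))
            assert m.spectral_radius() < 1

    def test_scale_edges_incident_selects_touching_edges(self):
        sc = default_scenario(seed=0)
        g = sc.base.coupling
        mods = dict(scale_edges_incident(g, {"Fp1"}, 0.4))
        ix = {lab: i for i, lab in enumerate(g.node_labels)}
        for e, f in mods.items():
            assert ix["Fp1"] in e and f == 0.4
        untouched = [e for e in g.edges if tuple(e) not in mods]
        for e in untouched:
            assert ix["Fp1"] not in e

    def test_62_channel_montage_supported(self):
        sc = default_scenario(n_channels=62, duration_s=2.0, seed=1)
        assert sc.base.spectral_radius() < 1
        assert len(sc.base.coupling.node_labels) == 62
        _, rec = generate_scenario(sc)[0]
        assert rec.data.shape == (62, 2000)

    def test_channel_rms_near_target(self):
        sc = default_scenario(duration_s=20.0, seed=4)
        _, rec = generate_scenario(sc)[0]
        rms = rec.data.std(axis=1)
        # Stationary normalisation targets 10 uV (plus ~2% background).
        assert np.all(rms > 7.0) and np.all(rms < 14.0)
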