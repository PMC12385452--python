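import numpy as np
import pytest

from cortsim import (
    NetworkConfig,
    PopulationParams,
    UpStateTargets,
    firing_rate,
    fixed_point_state,
    kna_current,
    kna_gate,
    leak_current,
    network_rhs,
    sodium_pump,
    solve_beta_gaba,
    synaptic_current,
    synaptic_kinetics_rhs,
)
from cortsim.model import NVAR, SYN_CHANNELS, ColumnState, syn_index


@pytest.fixture()
def net():
    return NetworkConfig(n_columns=1)


@pytest.fixture()
def pyramidal(net):
    return net.params.pyramidal


class TestFiringRate:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (-58.5, 15.0),  # half activation at threshold
            (100.0, 30.0),  # saturation
            (-58.5 + 6.7, 15.0 * (1.0 + np.tanh(np.pi / (2 * np.sqrt(3.0))))),
        ],
    )
    def test_known_values(self, pyramidal, v, expected):
        assert firing_rate(v, pyramidal) == pytest.approx(expected, rel=1e-9)

    def test_value_one_sigma_above_threshold(self, pyramidal):
        # direct evaluation: ~25.80 Hz one inverse-gain above threshold
        assert firing_rate(-51.8, pyramidal) == pytest.approx(25.80, abs=0.01)

    def test_bounded_and_strictly_increasing(self, pyramidal):
        v = np.linspace(-120.0, 20.0, 2000)
        q = firing_rate(v, pyramidal)
        assert np.all(q > 0.0) and np.all(q < pyramidal.qmax)
        assert np.all(np.diff(q) > 0.0)

    def test_invalid_population_params(self):
        with pytest.raises(ValueError):
            PopulationParams(qmax=-1.0, theta=-58.5, sigma=6.7, tau=30.0, e_leak=-66.0)


class TestCurrents:
    def test_leak_zero_at_reversal(self, pyramidal):
        assert leak_current(pyramidal.e_leak, pyramidal) == 0.0
        assert leak_current(-56.0, pyramidal, g_leak=1.0) == pytest.approx(10.0)

    def test_leak_sign_follows_driving_force(self, pyramidal):
        v = np.linspace(-90, -30, 50)
        assert np.all(np.sign(leak_current(v, pyramidal)) == np.sign(v - pyramidal.e_leak))

    def test_synaptic_current_zeros_and_value(self):
        assert synaptic_current(-60.0, 0.0, 1.0, 1.0, 0.0) == 0.0
        assert synaptic_current(0.0, 1.3, 2.0, 1.0, 0.0) == 0.0  # at reversal
        assert synaptic_current(-60.0, 1.0, 2.0, 1.0, 0.0) == pytest.approx(-120.0)

    def test_kna_gate_midpoint_and_monotonicity(self):
        assert kna_gate(38.7) == pytest.approx(0.185, rel=1e-12)
        na = np.linspace(1.0, 80.0, 300)
        w = kna_gate(na)
        assert np.all((w > 0) & (w < 0.37))
        assert np.all(np.diff(w) > 0)

    def test_kna_current_zero_at_reversal(self, net):
        ad = net.params.adaptation
        assert kna_current(ad.e_k, 15.0, ad, 30.0) == pytest.approx(0.0)

    def test_kna_rejects_nonpositive_sodium(self, net):
        with pytest.raises(ValueError):
            kna_current(-60.0, 0.0, net.params.adaptation, 30.0)


class TestSodiumPump:
    def test_zero_at_equilibrium(self, net):
        assert sodium_pump(9.5, net.params.adaptation) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_fifteen_millimolar(self, net):
        # 15^3 = 3375 makes the first term exactly 1/2
        expected = 0.09 * (0.5 - 9.5**3 / (9.5**3 + 3375.0))
        got = sodium_pump(15.0, net.params.adaptation)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.02677, abs=2e-5)

    def test_monotone_and_signed(self, net):
        ad = net.params.adaptation
        na = np.linspace(0.5, 60.0, 400)
        pump = sodium_pump(na, ad)
        assert np.all(np.diff(pump) > 0)
        assert np.all(pump[na < ad.na_eq] < 0)
        with pytest.raises(ValueError):
            sodium_pump(-1.0, ad)


class TestSynapticKinetics:
    def test_fixed_point(self):
        sd, sdd = synaptic_kinetics_rhs(2.0, 0.0, 2.0, 0.07)
        assert sd == 0.0 and sdd == 0.0

    def test_impulse_response_peaks_at_inverse_gamma(self):
        # integrate the critically damped pair from an impulse in s_dot;
        # the alpha-function response peaks at t = 1/gamma (~14.29 ms)
        gamma, dt = 0.07, 0.001
        s, sd = 0.0, 1.0
        peak_t, peak_s, t = 0.0, -1.0, 0.0
        for _ in range(40000):
            d1 = synaptic_kinetics_rhs(s, sd, 0.0, gamma)
            s1, sd1 = s + dt * d1[0], sd + dt * d1[1]
            d2 = synaptic_kinetics_rhs(s1, sd1, 0.0, gamma)
            s, sd = s + 0.5 * dt * (d1[0] + d2[0]), sd + 0.5 * dt * (d1[1] + d2[1])
            t += dt
            if s > peak_s:
                peak_s, peak_t = s, t
        assert peak_t == pytest.approx(1.0 / gamma, rel=1e-3)

    def test_step_response_converges_to_drive(self):
        gamma, dt, drive = 0.07, 0.01, 3.5
        s, sd = 0.0, 0.0
        for _ in range(60000):
            d1 = synaptic_kinetics_rhs(s, sd, drive, gamma)
            s1, sd1 = s + dt * d1[0], sd + dt * d1[1]
            d2 = synaptic_kinetics_rhs(s1, sd1, drive, gamma)
            s, sd = s + 0.5 * dt * (d1[0] + d2[0]), sd + 0.5 * dt * (d1[1] + d2[1])
        assert s == pytest.approx(drive, rel=1e-6)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            synaptic_kinetics_rhs(0.0, 0.0, 1.0, 0.0)


class TestNetworkRhs:
    def _random_state(self, rng, n_columns):
        x = np.zeros((n_columns, NVAR))
        x[:, 0] = rng.uniform(-70, -50, n_columns)
        x[:, 1] = rng.uniform(-70, -50, n_columns)
        x[:, 2] = rng.uniform(9, 20, n_columns)
        for name in SYN_CHANNELS:
            x[:, syn_index(name)[0]] = rng.uniform(0, 3, n_columns)
            x[:, syn_index(name)[1]] = rng.uniform(-0.1, 0.1, n_columns)
        return x

    def test_two_column_swap_symmetry(self):
        net = NetworkConfig(n_columns=2)
        x = self._random_state(np.random.default_rng(1), 2)
        dx = network_rhs(x, net)
        dx_swapped = network_rhs(x[::-1].copy(), net)
        np.testing.assert_allclose(dx_swapped, dx[::-1], rtol=0, atol=1e-14)

    def test_identical_columns_get_identical_derivatives(self):
        net = NetworkConfig(n_columns=2)
        x = self._random_state(np.random.default_rng(2), 1)
        x = np.repeat(x, 2, axis=0)
        dx = network_rhs(x, net)
        np.testing.assert_allclose(dx[0], dx[1], rtol=0, atol=1e-14)

    def test_decoupled_two_column_matches_one_column(self):
        """With zero inter-coupling the membrane, sodium and within-column
        synaptic dynamics of each column equal the one-column model; only
        the (now current-less) inter-channel bookkeeping differs."""
        net2 = NetworkConfig(n_columns=2).with_scaling(beta_inter=0.0)
        net1 = NetworkConfig(n_columns=1).with_scaling(beta_inter=0.0)
        x = self._random_state(np.random.default_rng(3), 2)
        dx2 = network_rhs(x, net2)
        ignore = {syn_index("px")[0], syn_index("px")[1],
                  syn_index("ix")[0], syn_index("ix")[1]}
        keep = [k for k in range(NVAR) if k not in ignore]
        for col in range(2):
            dx1 = network_rhs(x[col:col + 1], net1)
            np.testing.assert_allclose(dx2[col, keep], dx1[0, keep], rtol=0, atol=1e-14)

    def test_rejects_nonfinite_state_and_negative_stimulus(self):
        net = NetworkConfig(n_columns=1)
        x = np.zeros((1, NVAR))
        x[0, 2] = 10.0
        bad = x.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            network_rhs(bad, net)
        with pytest.raises(ValueError):
            network_rhs(x, net, stim_rate=-1.0)

    def test_calibrated_fixed_point_has_zero_rhs(self):
        net = NetworkConfig(n_columns=1)
        targets = UpStateTargets(v_p_star=-54.5, v_i_star=-53.0)
        res = solve_beta_gaba(targets, 3.0, 1.0, net)
        cal = net.with_scaling(beta_intra=3.0, beta_gaba_p=res.beta_gaba_p,
                               beta_gaba_i=res.beta_gaba_i)
        x = fixed_point_state(cal, targets)
        assert np.max(np.abs(network_rhs(x, cal))) < 1e-8


class TestConfig:
    def test_yaml_json_roundtrip(self):
        net = NetworkConfig(n_columns=2).with_scaling(beta_intra=4.0, beta_gaba_p=5.0)
        for text, loader in ((net.to_yaml(), NetworkConfig.from_yaml),
                             (net.to_json(), NetworkConfig.from_json)):
            back = loader(text)
            assert back == net

    def test_column_state_array_roundtrip(self):
        state = ColumnState(v_p=-60.0, v_i=-58.0, na=11.0)
        state.s["pp"] = 1.5
        x = state.to_array()
        back = ColumnState.from_array(x)
        assert back.v_p == -60.0 and back.s["pp"] == 1.5

    def test_invalid_column_count(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_columns=3)
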